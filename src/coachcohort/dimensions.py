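"""The four coaching dimensions.

Daily activity is tracked in all four; supervised assessments exist only for
Physical, Cognitive and Nutritional (social activity was recorded but never
formally assessed, so social improvement cannot be computed — only whether
social activity relates to improvement elsewhere).
"""

PHYSICAL = "physical"
COGNITIVE = "cognitive"
SOCIAL = "social"
NUTRITIONAL = "nutritional"

#: All coaching dimensions, in canonical display order.
DIMENSIONS: tuple[str, ...] = (PHYSICAL, COGNITIVE, SOCIAL, NUTRITIONAL)

#: Dimensions backed by a baseline/final assessment battery.
ASSESSED_DIMENSIONS: tuple[str, ...] = (PHYSICAL, COGNITIVE, NUTRITIONAL)

#: Special group token meaning "the entire cohort" in trajectory views.
ALL_PARTICIPANTS = "all"


def check_dimension(dimension: str, *, assessed_only: bool = False) -> str:
    from .errors import DataError

    allowed = ASSESSED_DIMENSIONS if assessed_only else DIMENSIONS
    if dimension not in allowed:
        raise DataError(
            f"unknown coaching dimension {dimension!r}; expected one of {allowed}"
        )
    return dimension
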