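"""Fixed vocabulary of vascular segments.

Ten arterial segments delineated on axial CT slices, plus the venous
blood-pool segments used for background activity measurement.
"""

from __future__ import annotations

ARTERIAL_SEGMENTS: tuple[str, ...] = (
    "left_carotid",
    "right_carotid",
    "ascending_aorta",
    "aortic_arch",
    "descending_aorta",
    "abdominal_aorta",
    "left_iliac",
    "right_iliac",
    "left_femoral",
    "right_femoral",
)

VENOUS_SEGMENTS: tuple[str, ...] = (
    "inferior_vena_cava",
    "superior_vena_cava",
)

#: Blood-pool regions usable as a TBR background.
BACKGROUND_REGIONS: tuple[str, ...] = (
    "ascending_aorta_blood_pool",
    "inferior_vena_cava",
    "superior_vena_cava",
)

ALL_SEGMENTS: tuple[str, ...] = ARTERIAL_SEGMENTS + VENOUS_SEGMENTS


def validate_segment(name: str) -> str:
    """Return *name* if it belongs to the segment vocabulary, else raise."""
    if name not in ALL_SEGMENTS and name not in BACKGROUND_REGIONS:
        raise ValueError(
            f"unknown vascular segment {name!r}; "
            f"expected one of {sorted(set(ALL_SEGMENTS + BACKGROUND_REGIONS))}"
        )
    return name
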