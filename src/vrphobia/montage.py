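"""10-20 montage conventions used throughout the pipeline.

Sidedness follows the standard 10-20 rule: odd-numbered electrodes sit over
the left hemisphere, even-numbered over the right, and labels ending in Z
lie on the midline.
"""

from __future__ import annotations

# Full 21-electrode clinical montage (monopolar, CZ reference at acquisition).
CHANNELS_21 = (
    "FP1", "FPZ", "FP2",
    "F7", "F3", "FZ", "F4", "F8",
    "T3", "C3", "CZ", "C4", "T4",
    "T5", "P3", "PZ", "P4", "T6",
    "O1", "OZ", "O2",
)

# The 18 channels retained for analysis, in canonical order.  CZ carries no
# information under a CZ-referenced montage, and FPZ/FZ sit on the midline
# away from the regions of interest.
CHANNELS_18 = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6", "PZ", "OZ",
)

# Homologous right-left derivation pairs used for interhemispheric asymmetry.
IHA_PAIRS = (
    ("FP2", "FP1"),
    ("F4", "F3"),
    ("C4", "C3"),
    ("P4", "P3"),
    ("O2", "O1"),
    ("F8", "F7"),
    ("T4", "T3"),
    ("T6", "T5"),
)


def hemisphere(label: str) -> str:
    """Return ``'left'``, ``'right'`` or ``'midline'`` for a 10-20 label."""
    label = label.strip().upper()
    if label.endswith("Z"):
        return "midline"
    digits = "".join(ch for ch in label if ch.isdigit())
    if not digits:
        raise ValueError(f"not a 10-20 label: {label!r}")
    return "right" if int(digits) % 2 == 0 else "left"
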