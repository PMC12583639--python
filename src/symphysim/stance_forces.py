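"""Packaged fixture: muscle forces active during single-leg stance.

Resultant forces (N) of the 27 pelvic-region muscles active when standing on
one limb during normal walking, as reported for the reference gait trial.
These magnitudes are used directly as nodal loads when the static-optimization
stage is bypassed.

A few entries in the source table contain typesetting artifacts (Roman-numeral
fragments such as ``13.I`` and ``27.IV``, and the spelling ``Iliacue``).  They
are stored verbatim in ``printed`` together with a best-reading numeric value
and an ``ambiguous`` flag rather than silently normalized.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["standing_muscle_forces", "MUSCLE_NAMES"]

# (name, printed force, best-reading value N, ambiguous)
_ROWS = [
    ("Adductor brevis", "0.00", 0.00, False),
    ("Adductor longus", "0.00", 0.00, False),
    ("Adductor magnus 1", "0.00", 0.00, False),
    ("Adductor magnus 2", "0.00", 0.00, False),
    ("Adductor magnus 3", "0.00", 0.00, False),
    ("Biceps femoris - long head", "0.02", 0.02, False),
    ("Biceps femoris - short head", "33.2", 33.2, False),
    ("Gluteus maximus 1", "47.8", 47.8, False),
    ("Gluteus maximus 2", "27.IV", 27.4, True),
    ("Gluteus maximus 3", "0.00", 0.00, False),
    ("Gluteus medius 1", "620.6", 620.6, False),
    ("Gluteus medius 2", "251.6", 251.6, False),
    ("Gluteus medius 3", "197.9", 197.9, False),
    ("Gluteus minimus 1", "71.5", 71.5, False),
    ("Gluteus minimus 2", "76.4", 76.4, False),
    ("Gluteus minimus 3", "77.5", 77.5, False),
    ("Gracilis", "0.00", 0.00, False),
    ("Iliacus", "37.2", 37.2, True),  # printed "Iliacue"
    ("Pectineus", "0.00", 0.00, False),
    ("Piriformis", "0.02", 0.02, False),
    ("Psoas major", "52.8", 52.8, False),
    ("Quadratus femoris", "0.00", 0.00, False),
    ("Rectus femoris", "43.5", 43.5, False),
    ("Sartorius", "13.I", 13.1, True),
    ("Semimembranosus", "0.03", 0.03, False),
    ("Semitendinosus", "0.01", 0.01, False),
    ("Tensor fasciae latae", "81.8", 81.8, False),
]

MUSCLE_NAMES = tuple(r[0] for r in _ROWS)


def standing_muscle_forces() -> pd.DataFrame:
    """The single-leg-stance muscle force table.

    Columns: ``name``, ``printed`` (verbatim source cell), ``force_N``
    (best-reading value), ``ambiguous`` (typesetting-artifact flag).
    Zero-force rows are preserved.
    """
    return pd.DataFrame(_ROWS, columns=["name", "printed", "force_N", "ambiguous"])
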