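"""Reference stress/displacement/strain overview values for the two load cases.

The source table of per-part results contains several typesetting-corrupted
cells (Roman-numeral fragments such as ``2.XI`` or ``II.45``).  Each cell is
stored verbatim together with a best-reading value and an ``ambiguous`` flag;
only unambiguous cells (the hip-bone reduced stresses 86.50 and 73.7 MPa and
the strain entries) should be used as fixtures.

The right-SIJ reaction components and their magnitude are reported separately
in the source text and are unambiguous.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reported_overview", "SIJ_REACTION_COMPONENTS_N", "SIJ_REACTION_MAGNITUDE_N"]

#: Right sacroiliac-joint reaction components (N) for the reaction-only case.
SIJ_REACTION_COMPONENTS_N = (-381.5, 463.0, -829.6)

#: Magnitude of the right-SIJ reaction, N.
SIJ_REACTION_MAGNITUDE_N = 1023.8

# (case, part, quantity, printed, best reading, ambiguous)
_CELLS = [
    ("reaction_only", "hip_bones", "sigma_red_MPa", "86.50", 86.50, False),
    ("reaction_only", "hip_bones", "u_mm", "2.XI", 2.11, True),
    ("reaction_only", "hip_bones", "eps_max", "1.81.10^-2", 1.81e-2, False),
    ("reaction_only", "hip_bones", "eps_min", "-2.18.10^-2", -2.18e-2, False),
    ("reaction_only", "pubic_symphysis", "sigma_red_MPa", "02.XI", 2.11, True),
    ("reaction_only", "pubic_symphysis", "u_mm", "I.83", 1.83, True),
    ("reaction_only", "pubic_symphysis", "eps_max", "3.28.10^-1", 3.28e-1, False),
    ("reaction_only", "pubic_symphysis", "eps_min", "-3.95.10^-2", -3.95e-2, False),
    ("muscles", "hip_bones", "sigma_red_MPa", "73.7", 73.7, False),
    ("muscles", "hip_bones", "u_mm", "II.45", 2.45, True),
    ("muscles", "hip_bones", "eps_max", "1.17.10^-2", 1.17e-2, False),
    ("muscles", "hip_bones", "eps_min", "-1.90.10^-2", -1.90e-2, False),
    ("muscles", "pubic_symphysis", "sigma_red_MPa", "03.II", 3.2, True),
    ("muscles", "pubic_symphysis", "u_mm", "I.31", 1.31, True),
    ("muscles", "pubic_symphysis", "eps_max", "4.61.10^-1", 4.61e-1, False),
    ("muscles", "pubic_symphysis", "eps_min", "-5.49.10^-2", -5.49e-2, False),
]


def reported_overview() -> pd.DataFrame:
    """Verbatim reference overview cells with best readings and ambiguity flags."""
    return pd.DataFrame(
        _CELLS, columns=["case", "part", "quantity", "printed", "value", "ambiguous"]
    )
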