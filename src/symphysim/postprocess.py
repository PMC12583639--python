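"""Reduction of FE solutions to reported quantities.

Computes the von Mises ("reduced") stress sigma_red, logarithmic principal
strains, displacement magnitudes and support reactions, and builds per-part
summary tables and load-case comparisons in the style of a stress/strain/
displacement overview table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solver import Solution, reaction_magnitude

__all__ = [
    "von_mises",
    "log_principal_strains",
    "PartSummary",
    "SolutionSummary",
    "CaseComparison",
    "summarize",
    "compare_cases",
    "report_table",
]


def von_mises(stress: np.ndarray) -> float | np.ndarray:
    """Von Mises (reduced) stress sigma_red of symmetric 3x3 stress tensor(s).

    sqrt(1/2 [(s11-s22)^2 + (s22-s33)^2 + (s33-s11)^2 + 6(s12^2+s23^2+s13^2)])
    """
    s = np.asarray(stress, dtype=float)
    single = s.ndim == 2
    s = s[None] if single else s
    if s.shape[-2:] != (3, 3):
        raise ValueError("expected 3x3 stress tensor(s)")
    if not np.allclose(s, np.swapaxes(s, -1, -2), rtol=0, atol=1e-8 * (1 + np.abs(s).max())):
        raise ValueError("stress tensor must be symmetric")
    d01 = s[:, 0, 0] - s[:, 1, 1]
    d12 = s[:, 1, 1] - s[:, 2, 2]
    d20 = s[:, 2, 2] - s[:, 0, 0]
    shear = s[:, 0, 1] ** 2 + s[:, 1, 2] ** 2 + s[:, 0, 2] ** 2
    out = np.sqrt(0.5 * (d01**2 + d12**2 + d20**2 + 6.0 * shear))
    return float(out[0]) if single else out


def log_principal_strains(disp_grad: np.ndarray) -> tuple:
    """Largest and smallest logarithmic principal strains from grad(u).

    The deformation gradient is ``F = I + grad(u)``; principal logarithmic
    strains are the eigenvalues of ``ln sqrt(F^T F) = 1/2 ln C``.

    Raises
    ------
    ValueError
        If det(F) <= 0 (inverted element).
    """
    H = np.asarray(disp_grad, dtype=float)
    single = H.ndim == 2
    H = H[None] if single else H
    F = H + np.eye(3)
    detF = np.linalg.det(F)
    if np.any(detF <= 0):
        raise ValueError(
            f"inverted element(s): non-positive det(F) at indices "
            f"{np.flatnonzero(detF <= 0)[:10].tolist()}"
        )
    C = np.einsum("eki,ekj->eij", F, F)
    w = np.linalg.eigvalsh(C)
    eps = 0.5 * np.log(w)
    e_max, e_min = eps[:, -1], eps[:, 0]
    if single:
        return float(e_max[0]), float(e_min[0])
    return e_max, e_min


@dataclass
class PartSummary:
    """Extrema of one model part (e.g. hip bones, pubic symphysis)."""

    max_sigma_red: float  # MPa
    max_displacement: float  # mm
    eps_max: float  # largest log principal strain
    eps_min: float  # smallest log principal strain
    p99_sigma_red: float  # 99th-percentile reduced stress (singularity guard)


@dataclass
class SolutionSummary:
    """Per-part extrema plus support reactions for one load case."""

    case: str
    parts: dict[str, PartSummary]
    reactions: dict[str, tuple] = field(default_factory=dict)  # set -> (vec3, magnitude)


def summarize(
    solution: Solution,
    mesh,
    part_map: dict[str, np.ndarray] | None = None,
    case: str = "case",
) -> SolutionSummary:
    """Reduce a solution to per-part maxima/minima and reactions.

    ``part_map`` maps part names to element index arrays; by default the
    bone regions form ``hip_bones`` and the disc region ``pubic_symphysis``.
    Stresses and strains are per-element, displacements per-node (nodes of
    the part's elements).  Alongside the maxima a 99th-percentile reduced
    stress is reported to flag single-element spikes at constrained nodes.
    """
    if part_map is None:
        part_map = {
            "hip_bones": mesh.region_elements("bone_left", "bone_right"),
            "pubic_symphysis": mesh.region_elements("disc"),
        }
    sig_vm = von_mises(solution.element_stress)
    parts = {}
    for name, els in part_map.items():
        els = np.asarray(els, dtype=int)
        if els.size == 0:
            raise ValueError(f"part {name!r} contains no elements")
        e_max, e_min = log_principal_strains(solution.disp_grad[els])
        nodes = np.unique(mesh.elements[els])
        u_mag = np.linalg.norm(solution.u[nodes], axis=1)
        parts[name] = PartSummary(
            max_sigma_red=float(sig_vm[els].max()),
            max_displacement=float(u_mag.max()),
            eps_max=float(e_max.max()),
            eps_min=float(e_min.min()),
            p99_sigma_red=float(np.percentile(sig_vm[els], 99)),
        )
    reactions = {
        name: (vec, reaction_magnitude(vec)) for name, vec in solution.reactions.items()
    }
    return SolutionSummary(case=case, parts=parts, reactions=reactions)


@dataclass
class CaseComparison:
    """Percent difference of one quantity between two load cases."""

    quantity: str
    value_a: float
    value_b: float
    base: str  # "a" or "b"
    percent: float  # 100 * (a - b) / base value

    def __post_init__(self):
        if self.base not in ("a", "b"):
            raise ValueError("base must be 'a' or 'b'")


def compare_cases(
    value_a: float, value_b: float, quantity: str = "value", base: str = "a"
) -> CaseComparison:
    """Percent difference ``100 (A - B) / base`` with the base stated explicitly."""
    base_value = value_a if base == "a" else value_b
    if base_value == 0:
        raise ZeroDivisionError("comparison base value is zero")
    pct = 100.0 * (value_a - value_b) / base_value
    return CaseComparison(quantity, float(value_a), float(value_b), base, float(pct))


def report_table(summaries: list[SolutionSummary]) -> pd.DataFrame:
    """Stress/displacement/strain overview table, one row per part and case.

    Columns: ``case, part, sigma_red_MPa, u_mm, eps_max, eps_min,
    p99_sigma_red_MPa``; serializes losslessly to CSV and renders to markdown
    via ``DataFrame.to_markdown``-free formatting (plain ``to_csv`` /
    ``to_string``).
    """
    if not summaries:
        raise ValueError("at least one summary required")
    rows = []
    for s in summaries:
        for part, p in s.parts.items():
            rows.append(
                {
                    "case": s.case,
                    "part": part,
                    "sigma_red_MPa": p.max_sigma_red,
                    "u_mm": p.max_displacement,
                    "eps_max": p.eps_max,
                    "eps_min": p.eps_min,
                    "p99_sigma_red_MPa": p.p99_sigma_red,
                }
            )
    return pd.DataFrame(rows)
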