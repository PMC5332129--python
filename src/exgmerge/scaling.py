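"""Wilson plots, Wilson B estimation, and the resolution-dependent
correction factor f = b - (b - 1) * q^2 / q_n^2.

Wilson-B convention used throughout: least-squares regression of
ln<I> on q = 1/d^2 over equal-count resolution shells, with
B = -2 * slope (equivalent to the textbook ln<I> = ln C - 2B sin^2(theta)/lambda^2
under sin^2(theta)/lambda^2 = q/4).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from exgmerge.symmetry import UnitCell, q_value


@dataclass(frozen=True)
class CorrectionParams:
    b: float
    q_n: float  # q of the highest-resolution reflection (max q in dataset)

    def __post_init__(self) -> None:
        if self.q_n <= 0:
            raise ValueError("q_n must be positive")


def correction_factor(q: float, params: CorrectionParams) -> float:
    """f(q) = b - (b - 1) q^2 / q_n^2; f(q_n) = 1 by construction."""
    if q < 0 or q > params.q_n * (1 + 1e-12):
        raise ValueError(
            f"q={q} outside [0, q_n={params.q_n}]: beyond declared resolution limit"
        )
    return params.b - (params.b - 1.0) * (q * q) / (params.q_n * params.q_n)


def correction_params_from_records(records, cell: UnitCell, b: float) -> CorrectionParams:
    """Build CorrectionParams with q_n taken from the dataset itself."""
    q_n = max(q_value(r.hkl if hasattr(r, "hkl") else r.asu_hkl, cell) for r in records)
    return CorrectionParams(b=b, q_n=q_n)


def apply_correction(records: Sequence, cell: UnitCell, params: CorrectionParams) -> list:
    """Multiply each record's intensity and sigma by f(q(hkl)).

    Works on any record with hkl (or asu_hkl), intensity/sigma fields;
    multiplicities are untouched.
    """
    out = []
    for r in records:
        hkl = r.hkl if hasattr(r, "hkl") else r.asu_hkl
        f = correction_factor(q_value(hkl, cell), params)
        if hasattr(r, "intensity"):
            out.append(replace(r, intensity=r.intensity * f, sigma=r.sigma * f))
        else:
            out.append(
                replace(r, i_ideal_mean=r.i_ideal_mean * f, i_ideal_sd=r.i_ideal_sd * f)
            )
    return out


@dataclass(frozen=True)
class WilsonFit:
    shell_q: np.ndarray
    shell_log_mean_i: np.ndarray
    slope: float
    intercept: float

    @property
    def wilson_b(self) -> float:
        return -2.0 * self.slope


def _record_arrays(records, cell: UnitCell) -> tuple[np.ndarray, np.ndarray]:
    q = np.array(
        [q_value(r.hkl if hasattr(r, "hkl") else r.asu_hkl, cell) for r in records]
    )
    i = np.array(
        [r.intensity if hasattr(r, "intensity") else r.i_ideal_mean for r in records]
    )
    return q, i


def wilson_fit(records: Sequence, cell: UnitCell, n_shells: int = 10) -> WilsonFit:
    """Fit ln<I> vs q over equal-count shells; B = -2 * slope.

    Shells whose mean intensity is non-positive are dropped; at least
    two positive shells are required.
    """
    q, i = _record_arrays(records, cell)
    order = np.argsort(q)
    q, i = q[order], i[order]
    shell_q = []
    shell_log_i = []
    for idx in np.array_split(np.arange(len(q)), n_shells):
        if idx.size == 0:
            continue
        mean_i = float(np.mean(i[idx]))
        if mean_i > 0:
            shell_q.append(float(np.mean(q[idx])))
            shell_log_i.append(np.log(mean_i))
    if len(shell_q) < 2:
        raise ValueError("need at least 2 shells with positive mean intensity")
    slope, intercept = np.polyfit(shell_q, shell_log_i, 1)
    return WilsonFit(
        shell_q=np.array(shell_q),
        shell_log_mean_i=np.array(shell_log_i),
        slope=float(slope),
        intercept=float(intercept),
    )


def solve_b_for_wilson(
    records: Sequence,
    cell: UnitCell,
    target_b: float,
    n_shells: int = 10,
    b_bracket: tuple[float, float] = (1.0, 10.0),
) -> float:
    """Root-find the correction b that makes the corrected Wilson B hit
    ``target_b`` (the reference procedure chose b by matching Wilson B
    between datasets)."""

    def gap(b: float) -> float:
        params = correction_params_from_records(records, cell, b)
        corrected = apply_correction(records, cell, params)
        return wilson_fit(corrected, cell, n_shells).wilson_b - target_b

    return float(optimize.brentq(gap, *b_bracket))
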