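"""Synthetic serial-crystallography observation generator with ground truth.

The statistical structure mirrors what the analysis assumes about real
serial snapshot data:

* every non-absent reflection's observations share one diffuse/background
  Gaussian response ``N(mu_b, sigma_b)`` plus an exponential Bragg tail
  whose mean follows a Wilson-like resolution falloff modulated by a
  log-normal per-reflection structure factor;
* systematically absent reflections sample pure background;
* "synchrotron" mode instead draws near-symmetric Gaussians whose means
  Wilson-decay, emulating single-crystal rotation data.

No physical diffraction effects (partiality, detector noise models) are
simulated — only the distributional shape the downstream fits consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from exgmerge.formats import Observation
from exgmerge.symmetry import XFEL_CELL, UnitCell, d_spacing, is_systematically_absent

MODES = ("sfx", "synchrotron")


@dataclass(frozen=True)
class SimulationSpec:
    n_reflections: int = 200
    cell: UnitCell = XFEL_CELL
    d_min: float = 3.5
    multiplicity_range: tuple[int, int] = (5, 160)
    mu_b: float = 0.0
    sigma_b: float = 600.0
    bragg_scale: float = 3000.0  # S in tau(hkl) = S * exp(-B/(2 d^2)) * lognormal
    b_true: float = 30.0
    lognormal_sd: float = 0.5
    absent_fraction: float = 0.1
    mode: str = "sfx"
    n_frames: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.sigma_b <= 0 or self.bragg_scale <= 0:
            raise ValueError("sigma_b and bragg_scale must be positive")
        if not 0 <= self.absent_fraction < 1:
            raise ValueError("absent_fraction must be in [0,1)")


def _pick_indices(spec: SimulationSpec, rng: np.random.Generator):
    """Choose unique ASU indices above the resolution limit, including a
    controlled share of systematically absent axial reflections."""
    cell, d_min = spec.cell, spec.d_min
    h_max = int(cell.a / d_min)
    k_max = int(cell.b / d_min)
    l_max = int(cell.c / d_min)
    n_absent = int(round(spec.absent_fraction * spec.n_reflections))
    n_present = spec.n_reflections - n_absent

    chosen: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int, int]] = set()
    # absent candidates: odd axial indices (screw-axis forbidden)
    axial = [(0, 0, l) for l in range(1, l_max + 1, 2)]
    axial += [(0, k, 0) for k in range(1, k_max + 1, 2)]
    axial += [(h, 0, 0) for h in range(1, h_max + 1, 2)]
    axial = [hkl for hkl in axial if d_spacing(hkl, cell) >= d_min]
    order = rng.permutation(len(axial))
    for idx in order[:n_absent]:
        chosen.append(axial[idx])
        seen.add(axial[idx])

    while len(chosen) < n_absent + n_present:
        h = int(rng.integers(0, h_max + 1))
        k = int(rng.integers(0, k_max + 1))
        l = int(rng.integers(0, l_max + 1))
        hkl = (h, k, l)
        if hkl == (0, 0, 0) or hkl in seen:
            continue
        if d_spacing(hkl, cell) < d_min:
            continue
        if is_systematically_absent(hkl):
            continue
        chosen.append(hkl)
        seen.add(hkl)
    return chosen


def simulate_dataset(spec: SimulationSpec) -> tuple[list[Observation], pd.DataFrame]:
    """Generate observations plus a ground-truth table.

    Returns (observations, truth) where the truth table carries one row
    per unique reflection: hkl, d, the true Bragg scale (tau for sfx
    mode, mean intensity for synchrotron mode) and the absence flag.
    """
    rng = np.random.default_rng(spec.seed)
    indices = _pick_indices(spec, rng)
    observations: list[Observation] = []
    truth_rows = []
    m_lo, m_hi = spec.multiplicity_range
    for hkl in indices:
        h, k, l = hkl
        d = d_spacing(hkl, spec.cell)
        absent = is_systematically_absent(hkl)
        m = int(rng.integers(m_lo, m_hi + 1))
        wilson = math.exp(-spec.b_true / (2.0 * d * d))
        sf = float(rng.lognormal(mean=0.0, sigma=spec.lognormal_sd))
        if spec.mode == "sfx":
            tau = spec.bragg_scale * wilson * sf
            base = rng.normal(spec.mu_b, spec.sigma_b, size=m)
            if absent:
                values = base
                true_scale = 0.0
            else:
                values = base + rng.exponential(tau, size=m)
                true_scale = tau
        else:  # synchrotron: near-symmetric Gaussian observations
            mean_i = spec.bragg_scale * wilson * sf
            if absent:
                mean_i = 0.0
            sigma_i = 0.1 * abs(mean_i) + 0.1 * spec.sigma_b
            values = rng.normal(mean_i, sigma_i, size=m)
            true_scale = mean_i
        frames = rng.integers(0, spec.n_frames, size=m)
        for v, fr in zip(values, frames):
            observations.append(
                Observation(f"frm_{fr:05d}", h, k, l, float(v), None)
            )
        truth_rows.append(
            {
                "h": h,
                "k": k,
                "l": l,
                "d": d,
                "true_scale": true_scale,
                "is_absent": absent,
                "multiplicity": m,
                "b_true": spec.b_true,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return observations, truth


def export_fixture(observations: Sequence[Observation], path) -> None:
    """Write observations as a flat-dialect table readable by
    :func:`exgmerge.formats.read_observation_table`; byte-stable for a
    fixed input sequence."""
    lines = ["# frame_id h k l intensity\n"]
    for o in observations:
        if o.sigma is None:
            lines.append(f"{o.frame_id} {o.h} {o.k} {o.l} {o.intensity!r}\n")
        else:
            lines.append(f"{o.frame_id} {o.h} {o.k} {o.l} {o.intensity!r} {o.sigma!r}\n")
    Path(path).write_text("".join(lines), encoding="utf-8")
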