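"""Orthorhombic reciprocal-space geometry, ASU mapping and absence rules.

Only Laue group mmm (space group P2(1)2(1)2(1)) is supported: the space
group is accepted as a parameter so the interface can grow, but anything
else is rejected.  Friedel pairs are merged; anomalous signal is ignored.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from exgmerge.errors import EmptyDatasetError
from exgmerge.formats import Observation

SUPPORTED_SPACE_GROUPS = ("P212121",)


def normalize_space_group(symbol: str) -> str:
    """Canonicalize a space-group symbol; reject unsupported groups."""
    canonical = re.sub(r"[\s_()]", "", symbol).upper().replace("P2$_1$", "")
    if canonical != "P212121":
        raise ValueError(
            f"unsupported space group {symbol!r}; only P212121 is implemented"
        )
    return "P212121"


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        if (self.alpha, self.beta, self.gamma) != (90.0, 90.0, 90.0):
            raise ValueError("only orthorhombic cells (90/90/90) are supported")


# The paper's XFEL case; used as the default throughout the CLI.
XFEL_CELL = UnitCell(57.9, 84.8, 384.3)


def d_spacing(hkl: Sequence[int], cell: UnitCell) -> float:
    """Interplanar spacing in Angstrom for an orthorhombic cell."""
    h, k, l = hkl
    if (h, k, l) == (0, 0, 0):
        raise ValueError("d-spacing undefined for (0,0,0)")
    inv_d2 = (h / cell.a) ** 2 + (k / cell.b) ** 2 + (l / cell.c) ** 2
    return 1.0 / math.sqrt(inv_d2)


def q_value(hkl: Sequence[int], cell: UnitCell) -> float:
    """Inverse resolution squared, q = 1/d^2 (Angstrom^-2)."""
    return 1.0 / d_spacing(hkl, cell) ** 2


def map_to_asu(hkl: Sequence[int]) -> tuple[int, int, int]:
    """Canonical mmm asymmetric-unit representative: (|h|, |k|, |l|).

    Point group 222 combined with Friedel inversion makes every sign
    combination equivalent, so the all-non-negative triple is canonical.
    """
    h, k, l = hkl
    if (h, k, l) == (0, 0, 0):
        raise ValueError("(0,0,0) is not a reflection")
    return (abs(h), abs(k), abs(l))


def is_systematically_absent(hkl: Sequence[int]) -> bool:
    """P2(1)2(1)2(1) screw-axis reflection conditions.

    Axial reflections h00, 0k0, 00l are present only for even indices;
    everything else is allowed.
    """
    h, k, l = map_to_asu(hkl)
    if k == 0 and l == 0:
        return h % 2 == 1
    if h == 0 and l == 0:
        return k % 2 == 1
    if h == 0 and k == 0:
        return l % 2 == 1
    return False


@dataclass
class ReflectionGroup:
    """All symmetry-equivalent observations mapped onto one ASU index."""

    asu_hkl: tuple[int, int, int]
    d_spacing: float
    is_absent: bool
    intensities: list[float] = field(default_factory=list)

    @property
    def q(self) -> float:
        return 1.0 / self.d_spacing**2

    @property
    def multiplicity(self) -> int:
        return len(self.intensities)


def group_observations(
    observations: Iterable[Observation], cell: UnitCell
) -> list[ReflectionGroup]:
    """Map observations to the ASU and collect them per unique reflection.

    Returns one group per distinct ASU index, sorted by (h,k,l); within
    each group the intensities preserve input order.  The sum of
    multiplicities always equals the number of input observations.
    """
    buckets: dict[tuple[int, int, int], list[float]] = {}
    count = 0
    for obs in observations:
        asu = map_to_asu(obs.hkl)
        buckets.setdefault(asu, []).append(obs.intensity)
        count += 1
    if count == 0:
        raise EmptyDatasetError("empty dataset: no observations to group")
    groups = [
        ReflectionGroup(
            asu_hkl=asu,
            d_spacing=d_spacing(asu, cell),
            is_absent=is_systematically_absent(asu),
            intensities=vals,
        )
        for asu, vals in buckets.items()
    ]
    groups.sort(key=lambda g: g.asu_hkl)
    return groups
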