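"""Reading unmerged observation tables and writing merged reflection files.

Two input dialects are supported:

``flat``
    Whitespace-separated columns ``frame_id h k l I [sigma]``; lines
    starting with ``#`` are comments.

``stream-lite``
    Per-frame blocks delimited by literal ``BEGIN_CHUNK <frame_id>`` /
    ``END_CHUNK`` lines, each containing ``h k l I [sigma]`` rows.  This is
    a deliberately minimal stand-in for full stream formats produced by
    integration pipelines.

Merged output is a plain-text hkl file: ``#``-prefixed header lines with
the unit cell, space group and column legend, then one row per unique
reflection ``h k l I sigma multiplicity`` sorted by (h, k, l).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

from exgmerge.errors import EmptyDatasetError

logger = logging.getLogger(__name__)

PathOrStream = Union[str, Path, IO[str]]

DIALECTS = ("flat", "stream-lite")


@dataclass(frozen=True)
class Observation:
    """One integrated spot measurement, pre-ASU mapping."""

    frame_id: str
    h: int
    k: int
    l: int
    intensity: float
    sigma: float | None = None

    def __post_init__(self) -> None:
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise ValueError("Miller index (0,0,0) is not a reflection")
        if not math.isfinite(self.intensity):
            raise ValueError(f"non-finite intensity {self.intensity!r}")
        if self.sigma is not None:
            if not math.isfinite(self.sigma) or self.sigma < 0:
                raise ValueError(f"invalid sigma {self.sigma!r}")

    @property
    def hkl(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)


@dataclass(frozen=True)
class MergedReflectionRecord:
    """One merged unique reflection: intensity, uncertainty, multiplicity."""

    h: int
    k: int
    l: int
    intensity: float
    sigma: float
    multiplicity: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be positive")

    @property
    def hkl(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)


def _open_text(source: PathOrStream) -> tuple[Iterator[str], bool]:
    if hasattr(source, "read"):
        return iter(source), False  # type: ignore[arg-type]
    handle = open(source, "r", encoding="utf-8")
    return iter(handle), True


def _parse_obs_fields(fields: Sequence[str], frame_id: str) -> Observation:
    h, k, l = (int(fields[0]), int(fields[1]), int(fields[2]))
    intensity = float(fields[3])
    sigma = float(fields[4]) if len(fields) > 4 else None
    return Observation(frame_id, h, k, l, intensity, sigma)


def read_observation_table(
    source: PathOrStream, dialect: str = "flat"
) -> list[Observation]:
    """Read unmerged observations from *source* in the given dialect.

    Malformed lines are skipped and counted (reported via logging); an
    input with zero valid observations raises :class:`EmptyDatasetError`.
    File order is preserved.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    lines, should_close = _open_text(source)
    observations: list[Observation] = []
    n_skipped = 0
    frame_id: str | None = None
    try:
        for raw in lines:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if dialect == "stream-lite":
                if line.startswith("BEGIN_CHUNK"):
                    parts = line.split(maxsplit=1)
                    frame_id = parts[1].strip() if len(parts) > 1 else ""
                    continue
                if line == "END_CHUNK":
                    frame_id = None
                    continue
                if frame_id is None:
                    n_skipped += 1
                    continue
                fields = line.split()
                if len(fields) < 4:
                    n_skipped += 1
                    continue
                try:
                    observations.append(_parse_obs_fields(fields[:5], frame_id))
                except (ValueError, TypeError):
                    n_skipped += 1
            else:
                fields = line.split()
                if len(fields) < 5:
                    n_skipped += 1
                    continue
                try:
                    observations.append(_parse_obs_fields(fields[1:6], fields[0]))
                except (ValueError, TypeError):
                    n_skipped += 1
    finally:
        if should_close:
            lines.close()  # type: ignore[attr-defined]
    if n_skipped:
        logger.warning("skipped %d malformed line(s)", n_skipped)
    if not observations:
        raise EmptyDatasetError("empty dataset: no valid observations found")
    logger.info("read %d observations (%d skipped)", len(observations), n_skipped)
    return observations


def write_merged(
    records: Iterable[MergedReflectionRecord],
    cell,
    destination: PathOrStream,
    space_group: str = "P212121",
) -> None:
    """Write merged reflections as a plain-text hkl file sorted by (h,k,l).

    Values are formatted with 6 significant digits; re-reading the file
    with :func:`read_merged` reproduces the records at that precision.
    A duplicate unique index raises ``ValueError``.
    """
    ordered = sorted(records, key=lambda r: (r.h, r.k, r.l))
    seen: set[tuple[int, int, int]] = set()
    for rec in ordered:
        if rec.hkl in seen:
            raise ValueError(f"duplicate unique reflection index {rec.hkl}")
        seen.add(rec.hkl)
    header = (
        f"# unit cell: a={cell.a:.6g} b={cell.b:.6g} c={cell.c:.6g} "
        f"alpha={cell.alpha:.6g} beta={cell.beta:.6g} gamma={cell.gamma:.6g}\n"
        f"# space group: {space_group}\n"
        "# h k l intensity sigma multiplicity\n"
    )
    body = "".join(
        f"{r.h} {r.k} {r.l} {r.intensity:.6g} {r.sigma:.6g} {r.multiplicity}\n"
        for r in ordered
    )
    if hasattr(destination, "write"):
        destination.write(header + body)  # type: ignore[union-attr]
    else:
        Path(destination).write_text(header + body, encoding="utf-8")


def read_merged(source: PathOrStream) -> list[MergedReflectionRecord]:
    """Read back a merged hkl file written by :func:`write_merged`."""
    lines, should_close = _open_text(source)
    records: list[MergedReflectionRecord] = []
    try:
        for raw in lines:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            records.append(
                MergedReflectionRecord(
                    h=int(fields[0]),
                    k=int(fields[1]),
                    l=int(fields[2]),
                    intensity=float(fields[3]),
                    sigma=float(fields[4]),
                    multiplicity=int(fields[5]),
                )
            )
    finally:
        if should_close:
            lines.close()  # type: ignore[attr-defined]
    if not records:
        raise EmptyDatasetError("empty dataset: no merged reflections found")
    return records
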