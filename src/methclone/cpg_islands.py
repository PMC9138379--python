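"""Sliding-window CpG island prediction.

A CpG island here is the classical Gardiner-Garden & Frommer notion: a
region of minimum length whose G+C fraction and CpG observed/expected
ratio both exceed thresholds. Windows of ``window`` bp are slid by
``step`` bp; passing windows are merged when they overlap or abut, merged
regions shorter than ``min_length`` are discarded, and the G+C and
obs/exp statistics are recomputed on each merged region (not averaged
over its windows). Islands are numbered 1-based by start coordinate,
matching the "Island 1 / Island 2" convention of promoter reports.

Defaults follow the published defaults of the standard bisulfite-primer
design tool: 100 bp window, 1 bp step, minimum length 100 bp, GC >= 0.50,
obs/exp >= 0.60. CpG is its own reverse complement, so scanning the top
strand suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seq_core import BedRecord, Interval, ReferenceLocus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IslandParams:
    """Thresholds for island calling (lengths in bp, gc/obs_exp as fractions)."""

    min_length: int = 100
    min_gc: float = 0.50
    min_obs_exp: float = 0.60
    window: int = 100
    step: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.window <= self.min_length:
            raise ValueError("require min_length >= window >= 1")
        if not 0.0 <= self.min_gc <= 1.0:
            raise ValueError("min_gc must be a fraction in [0, 1]")
        if self.min_obs_exp <= 0:
            raise ValueError("min_obs_exp must be positive")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass(frozen=True)
class CpGIsland:
    """A merged passing region with its ordinal rank and recomputed stats."""

    interval: Interval
    ordinal: int
    gc: float
    obs_exp: float

    @property
    def name(self) -> str:
        return f"Island {self.ordinal}"


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length with ``N`` excluded from numerator and denominator."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    n_valid = len(seq) - seq.count("N")
    if n_valid == 0:
        raise ValueError("all-N sequence: GC fraction undefined")
    return (seq.count("G") + seq.count("C")) / n_valid


def obs_exp_cpg(seq: str) -> float:
    """CpG observed/expected ratio: (#CG * length) / (#C * #G); 0 when #C*#G = 0."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    return seq.count("CG") * len(seq) / (n_c * n_g)


def _window_pass_mask(locus: ReferenceLocus, params: IslandParams) -> tuple[np.ndarray, np.ndarray]:
    """Boolean pass flag per window start, plus the array of starts."""
    seq = locus.sequence
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_g = arr == b"G"
    is_c = arr == b"C"
    is_n = arr == b"N"
    is_cg = np.zeros(len(seq), dtype=bool)
    if len(seq) > 1:
        is_cg[:-1] = is_c[:-1] & is_g[1:]

    w = params.window
    starts = np.arange(0, len(seq) - w + 1, params.step)
    # cumulative sums give O(1) per-window counts
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_n = np.concatenate([[0], np.cumsum(is_n)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    n_c = cum_c[starts + w] - cum_c[starts]
    n_g = cum_g[starts + w] - cum_g[starts]
    n_n = cum_n[starts + w] - cum_n[starts]
    # CG dinucleotides fully inside the window
    n_cg = cum_cg[starts + w - 1] - cum_cg[starts]

    n_valid = w - n_n
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(n_valid > 0, (n_c + n_g) / np.maximum(n_valid, 1), 0.0)
        oe = np.where(n_c * n_g > 0, n_cg * w / np.maximum(n_c * n_g, 1), 0.0)
    passing = (gc >= params.min_gc) & (oe >= params.min_obs_exp)
    return passing, starts


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting half-open intervals; idempotent."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def find_cpg_islands(
    locus: ReferenceLocus, params: IslandParams | None = None
) -> list[CpGIsland]:
    """Predict CpG islands on the top strand of ``locus``.

    Returns disjoint islands sorted by start, ordinals 1-based in start
    order. A locus shorter than the window yields an empty list with a
    logged warning.
    """
    params = params or IslandParams()
    if len(locus) < params.window:
        logger.warning(
            "locus %s (%d bp) shorter than window (%d bp); no islands called",
            locus.id, len(locus), params.window,
        )
        return []
    passing, starts = _window_pass_mask(locus, params)
    windows = [
        (int(s), int(s) + params.window) for s, ok in zip(starts, passing) if ok
    ]
    merged = [
        (s, e) for s, e in merge_intervals(windows) if e - s >= params.min_length
    ]
    islands = []
    for ordinal, (s, e) in enumerate(merged, start=1):
        sub = locus.sequence[s:e]
        islands.append(
            CpGIsland(
                interval=Interval(s, e),
                ordinal=ordinal,
                gc=gc_fraction(sub),
                obs_exp=obs_exp_cpg(sub),
            )
        )
    return islands


def islands_to_bed(locus: ReferenceLocus, islands: list[CpGIsland]) -> list[BedRecord]:
    return [
        BedRecord(
            chrom=locus.id,
            start=isl.interval.start,
            end=isl.interval.end,
            name=f"Island_{isl.ordinal}",
            score=f"{isl.obs_exp:.3f}",
        )
        for isl in islands
    ]
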