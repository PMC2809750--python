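"""Exclusion masks for methylation-prone promoter regions.

Promoter targets inside CpG islands, on CpG dinucleotides, or in GC-rich
stretches are avoided because DNA methylation at the target site
interferes with RNA activation. Island calling follows the
Gardiner-Garden & Frommer criteria (window length >= 200 bp, GC >= 50%,
observed/expected CpG >= 0.6 by default), implemented as the union of
all qualifying fixed-length windows; GC-rich masking is the analogous
union over a 100-bp / 60% GC sliding window by default. All thresholds
are configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_core import PromoterRecord

MASK_REASONS = ("cpg_island", "cpg_site", "gc_rich")


class MaskConfigError(ValueError):
    pass


@dataclass
class MaskSet:
    """Half-open 0-based excluded intervals, each tagged with a reason."""

    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end, reason in self.intervals:
            if reason not in MASK_REASONS:
                raise ValueError(f"unknown mask reason {reason!r}")
            if start < 0 or end < start:
                raise ValueError(f"bad interval ({start}, {end})")

    def overlaps(self, start: int, end: int) -> bool:
        """True iff [start, end) intersects any masked interval."""
        return any(start < e and s < end for s, e, _ in self.intervals)

    def total_masked(self) -> int:
        """Total masked bases (union over all reasons)."""
        covered: set[int] = set()
        for s, e, _ in self.intervals:
            covered.update(range(s, e))
        return len(covered)

    def merged(self) -> "MaskSet":
        """Merge overlapping/adjacent intervals within each reason class."""
        out: list[tuple[int, int, str]] = []
        for reason in MASK_REASONS:
            ours = sorted((s, e) for s, e, r in self.intervals if r == reason)
            for s, e in ours:
                if out and out[-1][2] == reason and s <= out[-1][1]:
                    out[-1] = (out[-1][0], max(out[-1][1], e), reason)
                else:
                    out.append((s, e, reason))
        return MaskSet(out)

    def __or__(self, other: "MaskSet") -> "MaskSet":
        return MaskSet(self.intervals + other.intervals).merged()

    def __len__(self) -> int:
        return len(self.intervals)

    def to_bed(self, path: str | Path, chrom: str) -> None:
        """Export as BED (0-based half-open; name column = reason tag)."""
        with open(path, "w") as fh:
            for s, e, reason in sorted(self.intervals):
                fh.write(f"{chrom}\t{s}\t{e}\t{reason}\n")


def _merge_windows(starts: np.ndarray, window: int, reason: str) -> MaskSet:
    """Union of equal-length qualifying windows given their start offsets."""
    if starts.size == 0:
        return MaskSet([])
    intervals: list[tuple[int, int, str]] = []
    run_start = prev = int(starts[0])
    for s in starts[1:]:
        s = int(s)
        if s <= prev + window:  # overlapping or adjacent windows
            prev = s
        else:
            intervals.append((run_start, prev + window, reason))
            run_start = prev = s
    intervals.append((run_start, prev + window, reason))
    return MaskSet(intervals)


def _window_counts(seq: str, window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window (#C, #G, #CG) via cumulative sums; one row per start."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(len(seq), dtype=np.int64)
    if len(seq) > 1:
        is_cg[:-1] = is_c[:-1] & is_g[1:]

    def windowed(x: np.ndarray, w: int) -> np.ndarray:
        cum = np.concatenate([[0], np.cumsum(x)])
        return cum[w:] - cum[: len(x) - w + 1]

    n_c = windowed(is_c, window)
    n_g = windowed(is_g, window)
    # a CpG is counted in a window iff both its bases are inside
    n_cg = windowed(is_cg, window - 1)[: len(seq) - window + 1] if window >= 2 else np.zeros(
        len(seq) - window + 1, dtype=np.int64
    )
    return n_c, n_g, n_cg


def find_cpg_islands(
    record: PromoterRecord,
    min_length: int = 200,
    min_gc: float = 50.0,
    min_obs_exp: float = 0.6,
) -> MaskSet:
    """CpG islands as the merged union of qualifying min_length windows.

    A window qualifies when GC% >= ``min_gc`` and observed/expected CpG
    = (#CG * window) / (#C * #G) >= ``min_obs_exp``. Sequences shorter
    than ``min_length`` yield an empty mask.
    """
    if min_length < 1:
        raise MaskConfigError(f"min_length must be >= 1, got {min_length}")
    seq = record.sequence
    if len(seq) < min_length:
        return MaskSet([])
    n_c, n_g, n_cg = _window_counts(seq, min_length)
    gc_ok = 100.0 * (n_c + n_g) / min_length >= min_gc
    denom = (n_c * n_g).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(denom > 0, n_cg * float(min_length) / denom, 0.0)
    starts = np.nonzero(gc_ok & (obs_exp >= min_obs_exp))[0]
    return _merge_windows(starts, min_length, "cpg_island")


def find_cpg_sites(record: PromoterRecord) -> MaskSet:
    """One 2-bp interval per CG dinucleotide on the sense strand."""
    seq = record.sequence
    intervals = [
        (i, i + 2, "cpg_site") for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"
    ]
    return MaskSet(intervals)


def find_gc_rich(record: PromoterRecord, window: int = 100, min_gc: float = 60.0) -> MaskSet:
    """Merged union of length-``window`` sliding windows with GC% >= min_gc."""
    seq = record.sequence
    if window < 1 or window > len(seq):
        raise MaskConfigError(
            f"window must be in [1, {len(seq)}], got {window}"
        )
    n_c, n_g, _ = _window_counts(seq, window)
    starts = np.nonzero(100.0 * (n_c + n_g) / window >= min_gc)[0]
    return _merge_windows(starts, window, "gc_rich")
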