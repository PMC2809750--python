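"""Cross-species target conservation and species-specific redesign.

A designed target is mapped onto an orthologous promoter as the best
ungapped 19-nt window (gapped alignment is deliberately out of scope: a
19-mer interrupted by an indel is not a usable saRNA target, and the
best gapless window simply reports low identity). Percent identity uses
the fixed target length 19 as denominator and is reported to one
decimal, rounded half away from zero — one substitution gives 94.7%,
three give 84.2%. When a human target is imperfectly conserved, a
species-specific duplex can be redesigned as the perfect complement of
the ortholog window; design-rule compliance of the redesigned target is
re-evaluated and reported, but not enforced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from .design_engine import (
    DesignConfig,
    SaRNADuplex,
    TargetCandidate,
    TARGET_LENGTH,
    build_duplex,
    evaluate_filters,
)
from .masking import MaskSet
from .sequence_core import PromoterRecord, TssCoordinate, to_tss_coordinate


@dataclass(frozen=True)
class ConservationReport:
    """How one designed target maps onto an orthologous promoter."""

    target_name: str
    ortholog_id: str
    target_dna: str
    mapped_offset: int
    per_position: tuple[bool, ...]  # 19 match calls, 5'->3' on the target
    n_matches: int
    perfect: bool

    @property
    def percent_identity(self) -> float:
        """100 * n_matches / 19, one decimal, half away from zero."""
        exact = Decimal(100 * self.n_matches) / Decimal(len(self.per_position))
        return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _matches(target: str, window: str) -> int:
    # N never matches anything, including N
    return sum(a == b and a != "N" for a, b in zip(target, window))


def map_target(
    target_dna: str,
    ortholog: PromoterRecord,
    search_window: tuple[int, int] | None = None,
    target_tss_position: int | None = None,
) -> int:
    """Offset of the best ungapped match of the target in the ortholog.

    Maximises the match count over all 19-nt windows (restricted to
    ``search_window`` offsets when given). Ties go to the window whose
    TSS-relative position is closest to ``target_tss_position`` (when
    supplied), then to the most upstream window.
    """
    target = target_dna.upper()
    L = len(target)
    seq = ortholog.sequence
    if len(seq) < L:
        raise ValueError(
            f"ortholog {ortholog.id!r} shorter ({len(seq)}) than the target ({L})"
        )
    lo, hi = 0, len(seq) - L
    if search_window is not None:
        lo, hi = max(lo, search_window[0]), min(hi, search_window[1])
        if lo > hi:
            raise ValueError(f"empty search window {search_window}")

    def tie_key(offset: int) -> tuple:
        if target_tss_position is not None:
            dist = abs(int(to_tss_coordinate(ortholog, offset)) - target_tss_position)
        else:
            dist = 0
        return (dist, offset)

    best_offset, best_score = lo, -1
    for offset in range(lo, hi + 1):
        score = _matches(target, seq[offset : offset + L])
        if score > best_score or (score == best_score and tie_key(offset) < tie_key(best_offset)):
            best_offset, best_score = offset, score
    return best_offset


def percent_identity(
    target_dna: str,
    ortholog: PromoterRecord,
    mapped_offset: int,
    target_name: str = "",
) -> ConservationReport:
    """Per-position match calls and identity over the mapped window."""
    target = target_dna.upper()
    L = len(target)
    if not 0 <= mapped_offset <= len(ortholog.sequence) - L:
        raise ValueError(
            f"window [{mapped_offset}, {mapped_offset + L}) outside ortholog "
            f"{ortholog.id!r}"
        )
    window = ortholog.sequence[mapped_offset : mapped_offset + L]
    calls = tuple(a == b and a != "N" for a, b in zip(target, window))
    n = sum(calls)
    return ConservationReport(
        target_name=target_name,
        ortholog_id=ortholog.id,
        target_dna=target,
        mapped_offset=mapped_offset,
        per_position=calls,
        n_matches=n,
        perfect=(n == L),
    )


def redesign_for_species(
    report: ConservationReport,
    ortholog: PromoterRecord,
    cfg: DesignConfig | None = None,
) -> tuple[SaRNADuplex, dict[str, bool]]:
    """Species-specific duplex perfectly complementary to the ortholog.

    The new target is the ortholog's own 19-mer at the mapped offset;
    the name is the original name suffixed with the species tag (e.g.
    ``dsNKX3-1-360-PT``). Hard-rule compliance is re-evaluated on the
    new target and returned as flags; violations warn but do not block.
    """
    if cfg is None:
        cfg = DesignConfig()
    offset = report.mapped_offset
    new_target = ortholog.sequence[offset : offset + TARGET_LENGTH]
    suffix = ortholog.species_tag or ortholog.id
    cand = TargetCandidate(
        promoter_id=ortholog.id,
        start_offset=offset,
        tss_position=to_tss_coordinate(ortholog, offset),
        target_dna=new_target,
        flank_3p=ortholog.sequence[offset + TARGET_LENGTH : offset + TARGET_LENGTH + 4],
    )
    evaluate_filters(cand, MaskSet([]), cfg)
    name = f"{report.target_name}-{suffix}" if report.target_name else f"ds{ortholog.id}-{suffix}"
    duplex = build_duplex(cand, cfg.overhang, name=name)
    failed = sorted(r for r, ok in cand.filter_flags.items() if not ok)
    if failed:
        warnings.warn(
            f"redesigned duplex {name}: design rules violated: {', '.join(failed)}",
            stacklevel=2,
        )
    return duplex, dict(cand.filter_flags)


def conservation_table(
    targets: pd.DataFrame,
    ortholog: PromoterRecord,
    cfg: DesignConfig | None = None,
    redesign: bool = True,
) -> pd.DataFrame:
    """Map every row of a design report onto one ortholog.

    ``targets`` needs columns name, target_dna and (optionally)
    tss_position for tie-breaking; returns one row per target with
    match statistics and, for imperfect matches, the redesigned
    species-specific duplex.
    """
    rows = []
    for _, row in targets.iterrows():
        tss_pos = int(row["tss_position"]) if "tss_position" in row else None
        offset = map_target(row["target_dna"], ortholog, target_tss_position=tss_pos)
        rep = percent_identity(row["target_dna"], ortholog, offset, target_name=row["name"])
        out = {
            "target_name": rep.target_name,
            "ortholog_id": rep.ortholog_id,
            "mapped_offset": rep.mapped_offset,
            "mapped_tss_position": int(to_tss_coordinate(ortholog, rep.mapped_offset)),
            "n_matches": rep.n_matches,
            "percent_identity": rep.percent_identity,
            "perfect": rep.perfect,
            "match_string": "".join("|" if m else "." for m in rep.per_position),
        }
        if redesign and not rep.perfect:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                duplex, flags = redesign_for_species(rep, ortholog, cfg)
            out["redesigned_name"] = duplex.name
            out["redesigned_sense"] = duplex.sense_strand
            out["redesigned_guide"] = duplex.guide_strand
            out["redesigned_rule_failures"] = ";".join(
                sorted(r for r, ok in flags.items() if not ok)
            )
        else:
            out["redesigned_name"] = ""
            out["redesigned_sense"] = ""
            out["redesigned_guide"] = ""
            out["redesigned_rule_failures"] = ""
        rows.append(out)
    return pd.DataFrame(rows)


def write_conservation_report(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
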