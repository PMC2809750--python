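"""saRNA target selection: scan, filter, score, rank, build duplexes.

The design procedure scans the sense strand of a promoter for 19-nt
windows lying entirely within a TSS-relative region (default -1200 to
-200), applies hard filters (GC 40-65%, no homopolymer run > 4,
3' end thermodynamically weaker than the 5' end, position 19 = A,
position 18 = A/T, no N, no overlap with methylation-prone masks, no
internal CpG), assigns weighted soft scores (position 18 preferably A,
position 7 preferably T, A/T-rich 3' flank, degree of end asymmetry),
and returns candidates sorted by sum score. Retained targets become
19-bp RNA duplexes with 2-nt 3' overhangs (dTdT or UU); the strand
complementary to the sense DNA target is the guide strand, so the 3'
end of the DNA target corresponds to the 5' end of the guide. Duplexes
are named ds<PROMOTER>-<position>, the position being the TSS-relative
coordinate of the target (5'-most base by default).

Rule positions (7, 18, 19, flank 20-23) are 1-based 5'->3' on the
sense-strand DNA target.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .masking import MaskSet, find_cpg_islands, find_cpg_sites, find_gc_rich
from .sequence_core import (
    PromoterRecord,
    TssCoordinate,
    dna_to_rna,
    gc_content,
    max_homopolymer_run,
    reverse_complement,
    to_tss_coordinate,
)
from .thermo import EndStability, NNTable, end_stability, load_nn_table, passes_asymmetry

TARGET_LENGTH = 19
FLANK_LENGTH = 4

HARD_RULES = (
    "gc_content",
    "homopolymer_run",
    "end_asymmetry",
    "pos19_a",
    "pos18_at",
    "no_n",
    "cpg_site",
    "mask_overlap",
)
SOFT_RULES = ("pos18_a", "pos7_t", "flank_at", "thermo_asymmetry")

DEFAULT_WEIGHTS = {
    "pos18_a": 1.0,
    "pos7_t": 1.0,
    "flank_at": 0.5,  # per A/T base among flank positions 20-23
    "thermo_asymmetry": 1.0,  # per kcal/mol of positive asymmetry
}


class DesignConfigError(ValueError):
    pass


@dataclass
class DesignConfig:
    """All tunables of the design procedure, YAML-serialisable.

    Region bounds are TSS-relative magnitudes in bp (the scanned region
    is [-region_upstream, -region_downstream]); GC bounds in percent;
    thermo_margin in kcal/mol.
    """

    region_upstream: int = 1200
    region_downstream: int = 200
    target_length: int = TARGET_LENGTH
    gc_min: float = 40.0
    gc_max: float = 65.0
    max_run: int = 4
    overhang: str = "dTdT"  # "dTdT" (deoxy) or "UU" (ribo)
    thermo_k: int = 5
    thermo_margin: float = 0.0
    thermo_params: str = "rna_xia_turner_1998"
    include_terminal_au: bool = False
    mask_cpg_islands: bool = True
    cpg_island_min_length: int = 200
    cpg_island_min_gc: float = 50.0
    cpg_island_min_obs_exp: float = 0.6
    cpg_site_mode: str = "per_candidate"  # per_candidate | interval | off
    mask_gc_rich: bool = True
    gc_rich_window: int = 100
    gc_rich_min_gc: float = 60.0
    name_anchor: str = "5p"  # anchor base for the name's position: 5p | 3p
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.target_length != TARGET_LENGTH:
            raise DesignConfigError("target_length is fixed at 19 nt")
        if not self.region_upstream > self.region_downstream >= 0:
            raise DesignConfigError(
                "need region_upstream > region_downstream >= 0, got "
                f"{self.region_upstream} / {self.region_downstream}"
            )
        if not self.gc_min < self.gc_max:
            raise DesignConfigError("need gc_min < gc_max")
        if self.overhang not in ("dTdT", "UU"):
            raise DesignConfigError(f"overhang must be dTdT or UU, got {self.overhang!r}")
        if self.cpg_site_mode not in ("per_candidate", "interval", "off"):
            raise DesignConfigError(f"bad cpg_site_mode {self.cpg_site_mode!r}")
        if self.name_anchor not in ("5p", "3p"):
            raise DesignConfigError(f"name_anchor must be 5p or 3p, got {self.name_anchor!r}")
        if any(w < 0 for w in self.weights.values()):
            raise DesignConfigError("weights must be non-negative")
        unknown = set(self.weights) - set(SOFT_RULES)
        if unknown:
            raise DesignConfigError(f"unknown weight keys {sorted(unknown)}")

    def nn_table(self) -> NNTable:
        return load_nn_table(self.thermo_params)

    def config_hash(self) -> str:
        """Short stable digest of the full configuration, recorded in
        every report so results are traceable to their settings."""
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise DesignConfigError(f"config file {path} is not a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise DesignConfigError(f"unknown config keys {sorted(unknown)}")
        if "weights" in raw:
            merged = dict(DEFAULT_WEIGHTS)
            merged.update(raw["weights"])
            raw["weights"] = merged
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class TargetCandidate:
    """One 19-nt sense-strand window with its filter and score state."""

    promoter_id: str
    start_offset: int
    tss_position: TssCoordinate  # of the 5'-most base
    target_dna: str
    flank_3p: str  # up to 4 bases 3' of the target (positions 20-23)
    filter_flags: dict[str, bool] = field(default_factory=dict)
    score_breakdown: dict[str, float] = field(default_factory=dict)
    sum_score: float = 0.0
    end_stab: EndStability | None = None

    @property
    def retained(self) -> bool:
        return bool(self.filter_flags) and all(self.filter_flags.values())

    @property
    def asymmetry(self) -> float:
        return self.end_stab.asymmetry if self.end_stab is not None else 0.0


@dataclass(frozen=True)
class SaRNADuplex:
    """A designed saRNA: 19 paired bases + 2-nt 3' overhang per strand.

    With the dTdT overhang the trailing "TT" letters denote
    deoxythymidines (``deoxy_overhang`` is True); with UU they are
    ribonucleotides like the rest of the strand.
    """

    name: str
    sense_strand: str
    guide_strand: str
    overhang: str

    @property
    def deoxy_overhang(self) -> bool:
        return self.overhang == "dTdT"


def build_masks(record: PromoterRecord, cfg: DesignConfig) -> MaskSet:
    """Compute the enabled exclusion masks for one promoter."""
    mask = MaskSet([])
    if cfg.mask_cpg_islands:
        mask = mask | find_cpg_islands(
            record,
            min_length=cfg.cpg_island_min_length,
            min_gc=cfg.cpg_island_min_gc,
            min_obs_exp=cfg.cpg_island_min_obs_exp,
        )
    if cfg.cpg_site_mode == "interval":
        mask = mask | find_cpg_sites(record)
    if cfg.mask_gc_rich and len(record.sequence) >= cfg.gc_rich_window:
        mask = mask | find_gc_rich(record, window=cfg.gc_rich_window, min_gc=cfg.gc_rich_min_gc)
    return mask


def enumerate_targets(record: PromoterRecord, cfg: DesignConfig) -> list[TargetCandidate]:
    """All 19-nt sense-strand windows fully inside the design region.

    A window qualifies when every base sits at a TSS position within
    [-region_upstream, -region_downstream]; candidates are emitted
    5'->3'. Returns an empty list (with a warning) when the region lies
    entirely outside the provided sequence.
    """
    seq = record.sequence
    L = cfg.target_length
    out: list[TargetCandidate] = []
    for start in range(0, len(seq) - L + 1):
        first = int(to_tss_coordinate(record, start))
        last = int(to_tss_coordinate(record, start + L - 1))
        if first < -cfg.region_upstream or last > -cfg.region_downstream or last > 0:
            continue
        out.append(
            TargetCandidate(
                promoter_id=record.id,
                start_offset=start,
                tss_position=TssCoordinate(first),
                target_dna=seq[start : start + L],
                flank_3p=seq[start + L : start + L + FLANK_LENGTH],
            )
        )
    if not out:
        warnings.warn(
            f"record {record.id!r}: design region [-{cfg.region_upstream}, "
            f"-{cfg.region_downstream}] is not covered by the sequence",
            stacklevel=2,
        )
    return out


def evaluate_filters(
    cand: TargetCandidate,
    masks: MaskSet,
    cfg: DesignConfig,
    params: NNTable | None = None,
) -> TargetCandidate:
    """Fill in filter_flags (and end stability) for one candidate."""
    t = cand.target_dna
    if params is None:
        params = cfg.nn_table()
    flags: dict[str, bool] = {}
    flags["no_n"] = "N" not in t
    flags["gc_content"] = cfg.gc_min <= gc_content(t) <= cfg.gc_max
    flags["homopolymer_run"] = max_homopolymer_run(t) <= cfg.max_run
    if flags["no_n"]:
        cand.end_stab = end_stability(
            t, k=cfg.thermo_k, params=params, include_terminal_au=cfg.include_terminal_au
        )
        flags["end_asymmetry"] = passes_asymmetry(cand.end_stab, cfg.thermo_margin)
    else:
        flags["end_asymmetry"] = False
    flags["pos19_a"] = t[18] == "A"
    flags["pos18_at"] = t[17] in "AT"
    flags["cpg_site"] = True if cfg.cpg_site_mode != "per_candidate" else "CG" not in t
    flags["mask_overlap"] = not masks.overlaps(
        cand.start_offset, cand.start_offset + cfg.target_length
    )
    cand.filter_flags = flags
    return cand


def apply_hard_filters(
    cands: Sequence[TargetCandidate],
    record: PromoterRecord,
    masks: MaskSet,
    cfg: DesignConfig,
) -> tuple[list[TargetCandidate], list[TargetCandidate]]:
    """Partition candidates into (retained, rejected), flags recorded on
    both. A candidate is retained iff every hard filter passes."""
    params = cfg.nn_table()
    retained: list[TargetCandidate] = []
    rejected: list[TargetCandidate] = []
    for cand in cands:
        evaluate_filters(cand, masks, cfg, params=params)
        (retained if cand.retained else rejected).append(cand)
    return retained, rejected


def score_target(cand: TargetCandidate, cfg: DesignConfig) -> TargetCandidate:
    """Weighted soft score: pos18 preferably A, pos7 preferably T,
    A/T-rich 3' flank (per base), and positive end asymmetry (per
    kcal/mol). Missing flank bases at the promoter edge score 0."""
    t = cand.target_dna
    w = cfg.weights
    breakdown = {
        "pos18_a": w.get("pos18_a", 0.0) * (1.0 if t[17] == "A" else 0.0),
        "pos7_t": w.get("pos7_t", 0.0) * (1.0 if t[6] == "T" else 0.0),
        "flank_at": w.get("flank_at", 0.0) * sum(b in "AT" for b in cand.flank_3p),
        "thermo_asymmetry": w.get("thermo_asymmetry", 0.0) * max(0.0, cand.asymmetry),
    }
    cand.score_breakdown = breakdown
    cand.sum_score = sum(breakdown.values())
    return cand


def rank_targets(cands: Sequence[TargetCandidate]) -> list[TargetCandidate]:
    """Deterministic total order: descending sum score, then greater
    asymmetry, then position closer to the TSS, then lexicographic
    target sequence."""
    return sorted(
        cands,
        key=lambda c: (
            -c.sum_score,
            -c.asymmetry,
            abs(int(c.tss_position)),
            c.target_dna,
        ),
    )


def name_duplex(promoter_id: str, tss_position: TssCoordinate | int) -> str:
    """Canonical saRNA name, e.g. ("P21", -322) -> "dsP21-322"."""
    value = int(tss_position)
    if value >= 0:
        raise ValueError(
            f"saRNA names require an upstream (negative) position, got {value:+d}"
        )
    return f"ds{promoter_id}-{abs(value)}"


def candidate_name(cand: TargetCandidate, cfg: DesignConfig) -> str:
    if cfg.name_anchor == "5p":
        pos = int(cand.tss_position)
    else:
        pos = int(cand.tss_position) + cfg.target_length - 1
        if pos >= 0:  # never happens for upstream-only windows
            pos += 1
    return name_duplex(cand.promoter_id, pos)


def build_duplex(cand: TargetCandidate, overhang: str = "dTdT", name: str | None = None) -> SaRNADuplex:
    """Assemble the saRNA duplex for a candidate target.

    sense = RNA copy of the target + overhang; guide = RNA reverse
    complement of the target + overhang, so that (ignoring overhangs)
    the 3' end of the DNA target pairs with the 5' end of the guide.
    """
    t = cand.target_dna
    if len(t) != TARGET_LENGTH or "N" in t:
        raise ValueError(f"invalid target for duplex assembly: {t!r}")
    if overhang not in ("dTdT", "UU"):
        raise ValueError(f"overhang must be dTdT or UU, got {overhang!r}")
    tail = "UU" if overhang == "UU" else "TT"
    sense = dna_to_rna(t) + tail
    guide = reverse_complement(dna_to_rna(t), alphabet="rna") + tail
    return SaRNADuplex(
        name=name if name is not None else name_duplex(cand.promoter_id, cand.tss_position),
        sense_strand=sense,
        guide_strand=guide,
        overhang=overhang,
    )


# ---------------------------------------------------------------------------
# Pipeline + report


REPORT_COLUMNS = [
    "name",
    "promoter_id",
    "tss_position",
    "start_offset",
    "end_offset",
    "target_dna",
    "sense_strand",
    "guide_strand",
    "overhang",
    "gc_percent",
    "max_run",
    "dg_5p",
    "dg_3p",
    "asymmetry",
    "retained",
    *[f"flag_{r}" for r in HARD_RULES],
    *[f"score_{r}" for r in SOFT_RULES],
    "sum_score",
    "config_hash",
]


def design_promoter(
    record: PromoterRecord, cfg: DesignConfig | None = None, all_candidates: bool = False
) -> pd.DataFrame:
    """Run the full design pipeline on one promoter.

    Returns the ranked report table: retained candidates sorted by sum
    score (rejected candidates appended, ranked among themselves, when
    ``all_candidates`` is set).
    """
    if cfg is None:
        cfg = DesignConfig()
    masks = build_masks(record, cfg)
    cands = enumerate_targets(record, cfg)
    retained, rejected = apply_hard_filters(cands, record, masks, cfg)
    for cand in retained + rejected:
        score_target(cand, cfg)
    ordered = rank_targets(retained)
    if all_candidates:
        ordered = ordered + rank_targets(rejected)
    cfg_hash = cfg.config_hash()
    rows = []
    for cand in ordered:
        duplex = (
            build_duplex(cand, cfg.overhang, name=candidate_name(cand, cfg))
            if "N" not in cand.target_dna
            else None
        )
        es = cand.end_stab
        rows.append(
            {
                "name": duplex.name if duplex else "",
                "promoter_id": cand.promoter_id,
                "tss_position": int(cand.tss_position),
                "start_offset": cand.start_offset,
                "end_offset": cand.start_offset + cfg.target_length,
                "target_dna": cand.target_dna,
                "sense_strand": duplex.sense_strand if duplex else "",
                "guide_strand": duplex.guide_strand if duplex else "",
                "overhang": cfg.overhang,
                "gc_percent": round(gc_content(cand.target_dna), 2),
                "max_run": max_homopolymer_run(cand.target_dna),
                "dg_5p": round(es.dg_5p, 2) if es else float("nan"),
                "dg_3p": round(es.dg_3p, 2) if es else float("nan"),
                "asymmetry": round(es.asymmetry, 2) if es else float("nan"),
                "retained": cand.retained,
                **{f"flag_{r}": cand.filter_flags[r] for r in HARD_RULES},
                **{f"score_{r}": cand.score_breakdown[r] for r in SOFT_RULES},
                "sum_score": cand.sum_score,
                "config_hash": cfg_hash,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


def write_targets_bed(report: pd.DataFrame, path: str | Path) -> None:
    """BED of retained targets (0-based half-open on the promoter)."""
    with open(path, "w") as fh:
        sub = report[report["retained"]]
        for _, row in sub.iterrows():
            fh.write(
                f"{row['promoter_id']}\t{row['start_offset']}\t{row['end_offset']}"
                f"\t{row['name']}\t{row['sum_score']:g}\t+\n"
            )
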