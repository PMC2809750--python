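"""Seeded synthetic promoters with planted, ground-truthed targets.

The generator emulates only the statistical structure the design rules
touch: background base composition (``base_gc``), CpG islands satisfying
the island-calling thresholds by construction, and planted 19-mers with
a known expected filter verdict — "auto" targets built to pass every
hard filter, and single-rule "decoy" targets built to fail exactly one
named rule while passing all others. Real promoter grammar (TATA boxes,
motif content, phylogenetic footprints) is deliberately absent.

Everything is driven by an explicit integer seed through one
numpy Generator per call; there is no global random state, and identical
(spec, seed) input yields byte-identical output on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design_engine import (
    DesignConfig,
    TargetCandidate,
    TARGET_LENGTH,
    build_masks,
    evaluate_filters,
)
from .masking import MaskSet
from .sequence_core import PromoterRecord, from_tss_coordinate
from .thermo import NNTable

# intrinsic rules: properties of the 19-mer alone, so decoys for them can
# be planted anywhere (mask overlap depends on context and is not
# plantable as a sequence property)
INTRINSIC_RULES = (
    "gc_content",
    "homopolymer_run",
    "end_asymmetry",
    "pos19_a",
    "pos18_at",
    "cpg_site",
)

BASES = np.array(list("ACGT"))


class SynthSpecError(ValueError):
    pass


@dataclass
class SynthSpec:
    """Recipe for one synthetic promoter.

    ``planted`` entries are ``(tss_position, what)`` where ``what`` is
    ``"auto"`` (a target passing every hard filter), ``"decoy:<rule>"``
    (fails exactly that intrinsic rule), or an explicit 19-mer;
    ``tss_position`` is the 5'-most base of the window. ``islands`` are
    ``(start_offset, length)`` CpG-island placements.
    """

    seed: int
    length: int = 2500
    base_gc: float = 45.0
    tss_index: int | None = None  # default: 200 bp of downstream sequence
    islands: list[tuple[int, int]] = field(default_factory=list)
    planted: list[tuple[int, str]] = field(default_factory=list)
    cpg_factor: float = 0.25  # background CpG depletion (obs/exp target)
    id: str = "SYN"

    def __post_init__(self) -> None:
        if self.tss_index is None:
            self.tss_index = max(1, self.length - 199)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw["islands"] = [tuple(x) for x in raw.get("islands", [])]
        raw["planted"] = [tuple(x) for x in raw.get("planted", [])]
        return cls(**raw)

    def validate(self, cfg: DesignConfig) -> None:
        if not 0 < self.base_gc < 100:
            raise SynthSpecError(f"base_gc must be in (0, 100), got {self.base_gc}")
        assert self.tss_index is not None
        anchor = self.tss_index - 1
        windows: list[tuple[int, int]] = []
        for pos, what in self.planted:
            if pos >= 0:
                raise SynthSpecError(f"planted position must be upstream, got {pos:+d}")
            start = anchor + pos
            end = start + TARGET_LENGTH
            if not (
                pos >= -cfg.region_upstream
                and pos + TARGET_LENGTH - 1 <= -cfg.region_downstream
            ):
                raise SynthSpecError(
                    f"planted target at {pos:+d} outside the design region "
                    f"[-{cfg.region_upstream}, -{cfg.region_downstream}]"
                )
            if start < 0 or end > self.length:
                raise SynthSpecError(f"planted target at {pos:+d} outside the sequence")
            for s, e in windows:
                if start < e and s < end:
                    raise SynthSpecError("planted targets overlap each other")
            windows.append((start, end))
            if isinstance(what, str) and what.startswith("decoy:"):
                rule = what.split(":", 1)[1]
                if rule not in INTRINSIC_RULES:
                    raise SynthSpecError(f"unknown decoy rule {rule!r}")
            elif what != "auto":
                if len(what) != TARGET_LENGTH or set(what.upper()) - set("ACGT"):
                    raise SynthSpecError(f"explicit planted target invalid: {what!r}")
        for istart, ilen in self.islands:
            if istart < 0 or istart + ilen > self.length:
                raise SynthSpecError(f"island ({istart}, {ilen}) outside the sequence")
            for s, e in windows:
                if istart < e and s < istart + ilen:
                    raise SynthSpecError("planted target overlaps an island")


def _rule_profile(
    target: str, cfg: DesignConfig, params: NNTable
) -> dict[str, bool]:
    """Intrinsic hard-filter verdicts of a bare 19-mer (no mask context)."""
    cand = TargetCandidate(
        promoter_id="_", start_offset=0, tss_position=None,  # type: ignore[arg-type]
        target_dna=target, flank_3p="",
    )
    evaluate_filters(cand, MaskSet([]), cfg, params=params)
    return {r: cand.filter_flags[r] for r in INTRINSIC_RULES}


def _draw(rng: np.random.Generator, n: int, gc: float) -> str:
    p_gc = gc / 200.0
    p_at = (100.0 - gc) / 200.0
    return "".join(rng.choice(BASES, size=n, p=[p_at, p_gc, p_gc, p_at]))


def _draw_background(rng: np.random.Generator, n: int, gc: float, cpg_factor: float) -> str:
    """First-order Markov draw with CpG dinucleotides suppressed by
    ``cpg_factor``, mimicking the CpG depletion of bulk genomic DNA
    outside islands (random i.i.d. sequence has obs/exp ~ 1, which would
    riddle any moderately GC-rich background with spurious islands)."""
    p = np.array([(100.0 - gc) / 200.0, gc / 200.0, gc / 200.0, (100.0 - gc) / 200.0])
    after_c = p.copy()
    after_c[2] *= cpg_factor  # index 2 = G
    after_c /= after_c.sum()
    u = rng.random(n)
    cum, cum_c = np.cumsum(p), np.cumsum(after_c)
    out = []
    prev = ""
    for i in range(n):
        b = BASES[np.searchsorted(cum_c if prev == "C" else cum, u[i], side="right")]
        out.append(b)
        prev = b
    return "".join(out)


def _sample_target(
    rng: np.random.Generator,
    cfg: DesignConfig,
    params: NNTable,
    fail_rule: str | None = None,
    max_iter: int = 50_000,
) -> str:
    """Rejection-sample a 19-mer whose intrinsic profile passes every
    rule, or (with ``fail_rule``) fails exactly that one rule."""
    for _ in range(max_iter):
        if fail_rule == "gc_content":
            body = _draw(rng, 17, 24.0)  # aim below gc_min
        elif fail_rule == "end_asymmetry":
            # strong 3' stacks, weak 5' stacks -> asymmetry <= 0
            body = _draw(rng, 5, 10.0) + _draw(rng, 9, 62.0) + _draw(rng, 3, 90.0)
        else:
            body = _draw(rng, 17, 52.0)
        pos18 = "CG"[rng.integers(2)] if fail_rule == "pos18_at" else "AT"[rng.integers(2)]
        pos19 = "CGT"[rng.integers(3)] if fail_rule == "pos19_a" else "A"
        target = body + pos18 + pos19
        if fail_rule == "homopolymer_run":
            i = int(rng.integers(0, 13))
            target = target[:i] + "AAAAA" + target[i + 5 : 17] + pos18 + pos19
        elif fail_rule == "cpg_site":
            i = int(rng.integers(0, 16))
            target = target[:i] + "CG" + target[i + 2 : 17] + pos18 + pos19
        profile = _rule_profile(target, cfg, params)
        if fail_rule is None:
            if all(profile.values()):
                return target
        elif not profile[fail_rule] and all(
            ok for r, ok in profile.items() if r != fail_rule
        ):
            return target
    raise SynthSpecError(
        f"could not sample a target (fail_rule={fail_rule!r}) in {max_iter} draws; "
        "the configured filters may make it infeasible"
    )


def _make_island(rng: np.random.Generator, length: int, cfg: DesignConfig) -> str:
    """A stretch qualifying as a CpG island under the configured
    thresholds: ~66% GC with a CpG planted every 6 bases."""
    for _ in range(100):
        seq = list(_draw(rng, length, 66.0))
        for i in range(0, length - 1, 6):
            seq[i], seq[i + 1] = "C", "G"
        s = "".join(seq)
        gc = 100.0 * (s.count("G") + s.count("C")) / length
        n_c, n_g, n_cg = s.count("C"), s.count("G"), s.count("CG")
        if (
            gc >= cfg.cpg_island_min_gc
            and n_c * n_g > 0
            and n_cg * length / (n_c * n_g) >= cfg.cpg_island_min_obs_exp
        ):
            return s
    raise SynthSpecError("could not construct a qualifying CpG island")


def generate_promoter(
    spec: SynthSpec, cfg: DesignConfig | None = None, max_attempts: int = 50
) -> tuple[PromoterRecord, pd.DataFrame]:
    """Generate a promoter and its planted-target ground truth.

    Planted "auto"/explicit-pass targets are guaranteed retained by the
    full pipeline under ``cfg`` (the background is re-drawn, still under
    the spec seed, if a stochastic mask happens to cover one); decoys
    are guaranteed to fail their named rule. The ground-truth table has
    one row per planted entry: tss_position, start_offset, target_dna,
    kind, expected_retained and expected_fail_flag.
    """
    if cfg is None:
        cfg = DesignConfig()
    spec.validate(cfg)
    params = cfg.nn_table()
    assert spec.tss_index is not None
    last_problem = ""
    for attempt in range(max_attempts):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.seed, attempt])))
        seq = list(_draw_background(rng, spec.length, spec.base_gc, spec.cpg_factor))
        for istart, ilen in spec.islands:
            seq[istart : istart + ilen] = _make_island(rng, ilen, cfg)
        rows = []
        for pos, what in spec.planted:
            if what == "auto":
                target = _sample_target(rng, cfg, params)
                kind, fail_flag, expect = "auto", "", True
            elif isinstance(what, str) and what.startswith("decoy:"):
                rule = what.split(":", 1)[1]
                target = _sample_target(rng, cfg, params, fail_rule=rule)
                kind, fail_flag, expect = f"decoy:{rule}", rule, False
            else:
                target = what.upper()
                profile = _rule_profile(target, cfg, params)
                failed = sorted(r for r, ok in profile.items() if not ok)
                kind = "explicit"
                fail_flag = failed[0] if failed else ""
                expect = not failed
            record_stub = PromoterRecord(spec.id, "A" * spec.length, spec.tss_index)
            start = from_tss_coordinate(record_stub, pos)
            seq[start : start + TARGET_LENGTH] = target
            rows.append(
                {
                    "tss_position": pos,
                    "start_offset": start,
                    "target_dna": target,
                    "kind": kind,
                    "expected_retained": expect,
                    "expected_fail_flag": fail_flag,
                }
            )
        record = PromoterRecord(
            id=spec.id, sequence="".join(seq), tss_index=spec.tss_index
        )
        truth = pd.DataFrame(
            rows,
            columns=[
                "tss_position",
                "start_offset",
                "target_dna",
                "kind",
                "expected_retained",
                "expected_fail_flag",
            ],
        )
        # context check: a retained-by-construction target must not be
        # shadowed by a stochastic mask from the background draw
        masks = build_masks(record, cfg)
        ok = True
        for row in truth.itertuples():
            if row.expected_retained and masks.overlaps(
                row.start_offset, row.start_offset + TARGET_LENGTH
            ):
                ok = False
                last_problem = f"mask covers planted target at {row.tss_position:+d}"
                break
        if ok:
            return record, truth
    raise SynthSpecError(
        f"could not realise spec after {max_attempts} attempts ({last_problem}); "
        "island/target placement may be too tight"
    )


def generate_ortholog(
    record: PromoterRecord,
    mutations: list[tuple[int, int]],
    seed: int,
    background_divergence: float = 0.0,
    species_tag: str | None = None,
) -> PromoterRecord:
    """Orthologous copy of a promoter with controlled divergence.

    ``mutations`` lists ``(tss_position, n_substitutions)`` per planted
    target (5'-most base convention): exactly n substitutions are placed
    uniformly at random inside that 19-nt window, never recreating the
    original base. ``background_divergence`` is the per-base substitution
    probability outside all listed windows.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed])))
    seq = list(record.sequence)
    protected: set[int] = set()

    def substitute(i: int) -> None:
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = choices[rng.integers(3)]

    for pos, n_subs in mutations:
        start = from_tss_coordinate(record, pos)
        window = range(start, start + TARGET_LENGTH)
        protected.update(window)
        if n_subs > TARGET_LENGTH:
            raise ValueError(f"cannot place {n_subs} substitutions in a 19-mer")
        for i in rng.choice(TARGET_LENGTH, size=n_subs, replace=False):
            substitute(start + int(i))
    if background_divergence > 0:
        hits = np.nonzero(rng.random(len(seq)) < background_divergence)[0]
        for i in hits:
            if int(i) not in protected:
                substitute(int(i))
    tag = species_tag or "ortholog"
    return PromoterRecord(
        id=f"{record.id}_{tag}",
        sequence="".join(seq),
        tss_index=record.tss_index,
        species_tag=species_tag,
    )


def default_spec(seed: int, base_gc: float = 45.0) -> SynthSpec:
    """A representative 2.5-kb promoter: one CpG island just upstream of
    the TSS, three pass-all targets and one decoy per intrinsic rule."""
    return SynthSpec(
        seed=seed,
        length=2500,
        base_gc=base_gc,
        islands=[(2120, 220)],
        planted=[
            (-1150, "auto"),
            (-760, "auto"),
            (-400, "auto"),
            (-1050, "decoy:gc_content"),
            (-950, "decoy:homopolymer_run"),
            (-860, "decoy:end_asymmetry"),
            (-660, "decoy:pos19_a"),
            (-560, "decoy:pos18_at"),
            (-470, "decoy:cpg_site"),
        ],
    )
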