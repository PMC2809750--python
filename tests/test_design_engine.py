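import itertools

import numpy as np
import pytest

from sarna_design.design_engine import (
    DesignConfig,
    DesignConfigError,
    TargetCandidate,
    apply_hard_filters,
    build_duplex,
    build_masks,
    design_promoter,
    enumerate_targets,
    name_duplex,
    rank_targets,
    score_target,
)
from sarna_design.masking import MaskSet
from sarna_design.sequence_core import (
    PromoterRecord,
    TssCoordinate,
    dna_to_rna,
    reverse_complement,
)
from sarna_design.thermo import EndStability, end_stability

from conftest import random_record


def make_candidate(target, flank="", pos=-500, asymmetry=None):
    cand = TargetCandidate(
        promoter_id="X",
        start_offset=0,
        tss_position=TssCoordinate(pos),
        target_dna=target,
        flank_3p=flank,
    )
    if asymmetry is not None:
        cand.end_stab = EndStability(dg_5p=-10.0, dg_3p=-10.0 + asymmetry, k=5)
    return cand


class TestConfig:
    def test_defaults_valid(self):
        cfg = DesignConfig()
        assert cfg.region_upstream == 1200 and cfg.region_downstream == 200
        assert cfg.gc_min == 40.0 and cfg.gc_max == 65.0 and cfg.max_run == 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"target_length": 21},
            {"region_upstream": 100, "region_downstream": 200},
            {"gc_min": 70.0},
            {"overhang": "AA"},
            {"weights": {"pos7_t": -1.0}},
            {"weights": {"nonsense": 1.0}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(DesignConfigError):
            DesignConfig(**kwargs)

    def test_yaml_round_trip_preserves_hash(self, tmp_path, cfg):
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert DesignConfig.from_yaml(path).config_hash() == cfg.config_hash()

    def test_partial_yaml_merges_weights(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("gc_min: 35\nweights:\n  pos7_t: 2.0\n")
        loaded = DesignConfig.from_yaml(path)
        assert loaded.gc_min == 35
        assert loaded.weights["pos7_t"] == 2.0
        assert loaded.weights["pos18_a"] == 1.0


class TestEnumeration:
    def test_candidate_count_over_full_region(self, cfg):
        # promoter spanning [-1500, +100]: 5'-most positions -1200..-218
        rng = np.random.default_rng(0)
        rec = PromoterRecord("X", "".join(rng.choice(list("ACGT"), size=1600)), 1501)
        cands = enumerate_targets(rec, cfg)
        assert len(cands) == 983
        assert int(cands[0].tss_position) == -1200
        assert int(cands[-1].tss_position) == -218
        assert all(len(c.target_dna) == 19 for c in cands)

    def test_promoter_not_covering_region_warns_and_is_empty(self, cfg):
        rec = PromoterRecord("X", "ACGT" * 50, 151)  # spans [-150, +50]
        with pytest.warns(UserWarning):
            assert enumerate_targets(rec, cfg) == []

    def test_flank_captured_from_sense_strand(self, cfg):
        rng = np.random.default_rng(1)
        rec = PromoterRecord("X", "".join(rng.choice(list("ACGT"), size=1600)), 1501)
        for cand in enumerate_targets(rec, cfg)[::97]:
            s = cand.start_offset
            assert cand.target_dna == rec.sequence[s : s + 19]
            assert cand.flank_3p == rec.sequence[s + 19 : s + 23]


class TestHardFilters:
    def compliant_target(self):
        # GC 8/19 = 42.1%, max run 2, no CG, pos18 T, pos19 A,
        # AT-rich 3' terminus (positive asymmetry)
        return "GGCCAGGCATCAGATAATA"

    def test_hand_built_compliant_candidate_retained(self, cfg):
        rec = PromoterRecord("X", "A" * 1600, 1501)
        cand = make_candidate(self.compliant_target())
        retained, rejected = apply_hard_filters([cand], rec, MaskSet([]), cfg)
        assert retained and not rejected
        assert all(cand.filter_flags.values())

    @pytest.mark.parametrize(
        "target,flag",
        [
            ("GGGGGCATCAGATCATATA", "homopolymer_run"),
            ("GGCCAGGCATCAGATAATG", "pos19_a"),
            ("GGCCAGGCATCAGATAGCA", "pos18_at"),
            ("GGGGCGGGCGGCCGCGGCA", "gc_content"),
            ("GGCCAGGCATCGGATAATA", "cpg_site"),
            ("GGCCAGGCATCANATAATA", "no_n"),
        ],
    )
    def test_single_rule_violations_flagged(self, cfg, target, flag):
        rec = PromoterRecord("X", "A" * 1600, 1501)
        cand = make_candidate(target)
        _, rejected = apply_hard_filters([cand], rec, MaskSet([]), cfg)
        assert rejected and rejected[0].filter_flags[flag] is False

    def test_mask_overlap_rejects(self, cfg):
        rec = PromoterRecord("X", "A" * 1600, 1501)
        cand = make_candidate(self.compliant_target())
        mask = MaskSet([(10, 12, "cpg_site")])  # candidate occupies [0, 19)
        _, rejected = apply_hard_filters([cand], rec, mask, cfg)
        assert rejected and rejected[0].filter_flags["mask_overlap"] is False


class TestScoring:
    def test_hand_summed_full_bonus(self, cfg):
        # pos18=A, pos7=T, flank ATTA, zero asymmetry -> 1 + 1 + 4*0.5
        cand = make_candidate("GGCCAGTCATCAGATCAAA", flank="ATTA", asymmetry=0.0)
        score_target(cand, cfg)
        assert cand.sum_score == pytest.approx(4.0)
        assert cand.score_breakdown["pos18_a"] == 1.0
        assert cand.score_breakdown["pos7_t"] == 1.0
        assert cand.score_breakdown["flank_at"] == 2.0

    def test_no_bonus_earned(self, cfg):
        cand = make_candidate("GGCCAGGCATCAGATCATA", flank="GCGC", asymmetry=0.0)
        score_target(cand, cfg)
        assert cand.sum_score == 0.0

    def test_missing_flank_scores_zero_for_missing_positions(self, cfg):
        cand = make_candidate("GGCCAGTCATCAGATCAAA", flank="AT", asymmetry=0.0)
        score_target(cand, cfg)
        assert cand.score_breakdown["flank_at"] == 1.0

    def test_doubling_weights_doubles_scores(self, cfg):
        doubled = DesignConfig(weights={k: 2 * v for k, v in cfg.weights.items()})
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = "".join(rng.choice(list("ACGT"), size=19))
            c1 = make_candidate(t, flank="ATGC", asymmetry=float(rng.normal()))
            c2 = make_candidate(t, flank="ATGC", asymmetry=c1.end_stab.asymmetry)
            score_target(c1, cfg)
            score_target(c2, doubled)
            assert c2.sum_score == pytest.approx(2 * c1.sum_score)

    def test_sum_equals_breakdown_total(self, cfg):
        cand = make_candidate("GGCCAGTCATCAGATCAAA", flank="ATTA", asymmetry=1.7)
        score_target(cand, cfg)
        assert cand.sum_score == pytest.approx(sum(cand.score_breakdown.values()))


class TestRanking:
    def test_descending_by_score(self):
        cands = [make_candidate("A" * 19, asymmetry=0.0) for _ in range(3)]
        for c, s in zip(cands, (2.0, 5.0, 3.0)):
            c.sum_score = s
        assert [c.sum_score for c in rank_targets(cands)] == [5.0, 3.0, 2.0]

    def test_tie_broken_by_asymmetry_then_tss_proximity(self):
        a = make_candidate("A" * 19, pos=-900, asymmetry=1.0)
        b = make_candidate("A" * 19, pos=-900, asymmetry=0.2)
        c = make_candidate("A" * 19, pos=-300, asymmetry=0.2)
        for x in (a, b, c):
            x.sum_score = 2.0
        assert rank_targets([c, b, a]) == [a, c, b]

    def test_deterministic_total_order(self):
        rng = np.random.default_rng(4)
        cands = []
        for _ in range(100):
            c = make_candidate(
                "".join(rng.choice(list("ACGT"), size=19)),
                pos=int(rng.integers(-1200, -219)),
                asymmetry=float(rng.normal()),
            )
            c.sum_score = float(rng.integers(0, 4))
            cands.append(c)
        first = rank_targets(list(cands))
        second = rank_targets(list(reversed(cands)))
        assert [c.target_dna for c in first] == [c.target_dna for c in second]


class TestNaming:
    @pytest.mark.parametrize(
        "pid,pos,expected",
        [("P21", -322, "dsP21-322"), ("VEGF", -706, "dsVEGF-706"), ("X", -200, "dsX-200")],
    )
    def test_canonical_names(self, pid, pos, expected):
        assert name_duplex(pid, pos) == expected

    @pytest.mark.parametrize("pos", [1, 50])
    def test_downstream_positions_rejected(self, pos):
        with pytest.raises(ValueError):
            name_duplex("X", pos)


class TestDuplex:
    def test_hand_computed_uu_duplex(self):
        cand = make_candidate("GCGCAAATTTACGTACGTA")
        duplex = build_duplex(cand, "UU")
        assert duplex.sense_strand == "GCGCAAAUUUACGUACGUAUU"
        assert duplex.guide_strand == "UACGUACGUAAAUUUGCGCUU"
        assert not duplex.deoxy_overhang

    def test_dtdt_overhang_is_deoxy_flagged(self):
        cand = make_candidate("GCGCAAATTTACGTACGTA")
        duplex = build_duplex(cand, "dTdT")
        assert duplex.sense_strand.endswith("TT")
        assert duplex.guide_strand.endswith("TT")
        assert duplex.deoxy_overhang

    def test_random_targets_form_perfect_watson_crick_duplex(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            t = "".join(rng.choice(list("ACGT"), size=19))
            duplex = build_duplex(make_candidate(t), "UU")
            # ignoring overhangs, guide is the RNA reverse complement:
            # the 3' end of the DNA target pairs with the guide's 5' end
            assert duplex.guide_strand[:-2] == reverse_complement(
                dna_to_rna(t), alphabet="rna"
            )
            pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
            sense = duplex.sense_strand[:-2]
            guide = duplex.guide_strand[:-2][::-1]
            assert all((s, g) in pairs for s, g in zip(sense, guide))


class TestPipeline:
    def test_retained_rows_pass_every_hard_rule(self, synthetic_promoter, cfg):
        record, _ = synthetic_promoter
        report = design_promoter(record, cfg)
        assert len(report) > 0
        assert report["retained"].all()
        flag_cols = [c for c in report.columns if c.startswith("flag_")]
        assert report[flag_cols].all().all()

    def test_all_candidates_mode_includes_rejected(self, synthetic_promoter, cfg):
        record, _ = synthetic_promoter
        full = design_promoter(record, cfg, all_candidates=True)
        kept = design_promoter(record, cfg)
        assert len(full) > len(kept)
        assert (~full["retained"]).any()

    def test_report_sorted_by_sum_score(self, synthetic_promoter, cfg):
        record, _ = synthetic_promoter
        report = design_promoter(record, cfg)
        scores = report["sum_score"].to_numpy()
        assert (np.diff(scores) <= 1e-12).all()

    def test_brute_force_retained_set_equivalence(self, cfg, rna_table):
        # independent predicate evaluation over every window
        rng = np.random.default_rng(17)
        rec = random_record(rng, 1800)
        masks = build_masks(rec, cfg)
        report = design_promoter(rec, cfg, all_candidates=True)
        got = set(report[report["retained"]]["start_offset"])
        expected = set()
        anchor = rec.tss_index - 1
        for s in range(len(rec.sequence) - 18):
            t = rec.sequence[s : s + 19]
            pos5 = s - anchor if s < anchor else s - anchor + 1
            pos3 = pos5 + 18
            if pos5 < -1200 or pos3 > -200 or pos3 >= 0:
                continue
            gc = 100 * sum(b in "GC" for b in t) / 19
            run = max(sum(1 for _ in grp) for _, grp in itertools.groupby(t))
            es = end_stability(t, k=5, params=rna_table)
            if (
                "N" not in t
                and 40 <= gc <= 65
                and run <= 4
                and es.asymmetry > 0
                and t[18] == "A"
                and t[17] in "AT"
                and "CG" not in t
                and not masks.overlaps(s, s + 19)
            ):
                expected.add(s)
        assert got == expected
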