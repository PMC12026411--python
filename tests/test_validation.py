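"""PCR fragment conversion, offset scoring and genotype concordance."""

import numpy as np
import pytest

from scetr.genotype_qc import GenotypeTable
from scetr.synthetic_data import SimulationConfig, simulate_truthset
from scetr.validation import (
    ValidationError,
    apply_offsets,
    concordance,
    pcr_to_repeats,
    score_offsets,
)


def table(a1, a2, ids=None):
    a1, a2 = np.asarray(a1, float), np.asarray(a2, float)
    return GenotypeTable(
        samples=[f"s{i}" for i in range(a1.shape[0])],
        variant_ids=ids or [f"L{j}" for j in range(a1.shape[1])],
        kind="tr", allele1=a1, allele2=a2,
    )


class TestPcrToRepeats:
    @pytest.mark.parametrize(
        "w,l,s,r,expected",
        [
            (103, 100, 3, 10, 11),   # exact whole-motif difference
            (100, 100, 3, 10, 10),   # reference-length fragment
            (104, 100, 3, 10, 11),   # 11.33 floored to 11
            (97, 100, 3, 10, 9),
        ],
    )
    def test_formula(self, w, l, s, r, expected):
        assert pcr_to_repeats(w, l, s, r) == expected

    def test_negative_result_masked(self):
        assert pcr_to_repeats(10, 100, 3, 2) is None

    def test_invalid_motif_length(self):
        with pytest.raises(ValidationError):
            pcr_to_repeats(100, 100, 0, 10)


class TestScoreOffsets:
    def test_full_recovery_credit_one(self):
        comps = {"L": {"c1": [((10, 12), (11, 13))] * 20}}
        rep = score_offsets(comps)
        score = {(s.offset): s.score_sum for s in rep.scores}
        assert score[1] == pytest.approx(20 * 1.0)
        assert rep.adopted["L"] == 1

    def test_homozygous_partial_credit_half(self):
        comps = {"L": {"c1": [((10, 10), (11, 12))] * 20}}
        rep = score_offsets(comps)
        score = {s.offset: s.score_sum for s in rep.scores}
        assert score[1] == pytest.approx(20 * 0.5)
        assert score[2] == pytest.approx(20 * 0.5)

    def test_heterozygous_partial_credit_quarter(self):
        comps = {"L": {"c1": [((10, 12), (11, 14))] * 20}}
        rep = score_offsets(comps)
        score = {s.offset: s.score_sum for s in rep.scores}
        assert score[1] == pytest.approx(20 * 0.25)

    def test_under_20_calls_not_adopted(self):
        comps = {"L": {"c1": [((10, 12), (11, 13))] * 19}}
        rep = score_offsets(comps)
        assert "L" not in rep.adopted
        assert rep.per_caller_top[("L", "c1")] == 1

    def test_callers_must_agree(self):
        good = [((10, 12), (11, 13))] * 20
        other = [((10, 12), (12, 14))] * 20  # offset +2 for this caller
        rep = score_offsets({"L": {"c1": good, "c2": other}})
        assert "L" not in rep.adopted
        rep2 = score_offsets({"L": {"c1": good, "c2": good}})
        assert rep2.adopted["L"] == 1

    def test_concordant_only_locus_top_offset_zero(self):
        comps = {"L": {"c1": [((10, 12), (10, 12))] * 25}}
        rep = score_offsets(comps)
        assert rep.adopted["L"] == 0

    def test_adopted_offset_improves_strict_concordance(self):
        caller = table([[10], [11], [12]] * 10, [[12], [13], [14]] * 10)
        truth = table([[11], [12], [13]] * 10, [[13], [14], [15]] * 10)
        comps = {"L0": {"c": [
            ((caller.allele1[i, 0], caller.allele2[i, 0]),
             (truth.allele1[i, 0], truth.allele2[i, 0]))
            for i in range(30)
        ]}}
        rep = score_offsets(comps)
        assert rep.adopted["L0"] == 1
        _, before = concordance(caller, truth)
        corrected = apply_offsets(truth, rep.adopted)
        _, after = concordance(caller, corrected)
        assert after["strict_concordance"] >= before["strict_concordance"]
        assert after["strict_concordance"] == 1.0


class TestConcordance:
    def test_identical_tables(self, rng):
        a1 = rng.integers(8, 15, size=(20, 3)).astype(float)
        a2 = rng.integers(8, 15, size=(20, 3)).astype(float)
        t = table(a1, a2)
        _, agg = concordance(t, t)
        assert agg["strict_concordance"] == 1.0
        assert agg["tolerant_concordance"] == 1.0

    def test_off_by_one_everywhere(self):
        truth = table([[10]] * 10, [[12]] * 10)
        caller = table([[10]] * 10, [[13]] * 10)  # summed dosage +1
        _, agg = concordance(caller, truth)
        assert agg["strict_concordance"] == 0.0
        assert agg["tolerant_concordance"] == 1.0

    def test_pair_mode_stricter_than_dosage(self):
        truth = table([[10]], [[12]])
        caller = table([[11]], [[11]])  # same summed dosage, different pair
        _, agg_d = concordance(caller, truth, mode="dosage")
        _, agg_p = concordance(caller, truth, mode="pair")
        assert agg_d["strict_concordance"] == 1.0
        assert agg_p["strict_concordance"] == 0.0

    def test_no_shared_calls_rejected(self):
        a = table([[10]], [[10]], ids=["A"])
        b = table([[10]], [[10]], ids=["B"])
        with pytest.raises(ValidationError):
            concordance(a, b)


class TestTruthsetIntegration:
    def test_zero_offsets_zero_errors_perfect(self):
        cfg = SimulationConfig(seed=11, n_cohorts=1, n_samples_per_cohort=40,
                               n_tr_loci=3, n_snv_loci=3)
        caller, truth, _ = simulate_truthset(cfg)
        _, agg = concordance(caller, truth)
        assert agg["strict_concordance"] == 1.0

    def test_constant_offset_locus(self):
        cfg = SimulationConfig(seed=11, n_cohorts=1, n_samples_per_cohort=40,
                               n_tr_loci=3, n_snv_loci=3)
        caller, truth, offset_map = simulate_truthset(cfg, offsets={0: 1})
        per_locus, _ = concordance(caller, truth, mode="pair")
        shifted = per_locus[0]
        assert shifted.strict_concordance == 0.0
        # each allele off by exactly 1: fully tolerant in pair mode
        assert shifted.tolerant_concordance == 1.0
        assert per_locus[1].strict_concordance == 1.0
        # on the summed dosage the shift is 2 repeats, so not tolerant
        per_dosage, _ = concordance(caller, truth, mode="dosage")
        assert per_dosage[0].tolerant_concordance == 0.0

    def test_planted_offset_recovered_end_to_end(self):
        cfg = SimulationConfig(seed=13, n_cohorts=1, n_samples_per_cohort=50,
                               n_tr_loci=2, n_snv_loci=2)
        caller, truth, offset_map = simulate_truthset(cfg, offsets={0: 2})
        comps = {
            locus: {"c": [
                ((caller.allele1[i, j], caller.allele2[i, j]),
                 (truth.allele1[i, j], truth.allele2[i, j]))
                for i in range(caller.n_samples)
            ]}
            for j, locus in enumerate(caller.variant_ids)
        }
        rep = score_offsets(comps)
        assert rep.adopted[caller.variant_ids[0]] == 2
        assert rep.adopted[caller.variant_ids[1]] == 0

    def test_known_error_rate_matches_strict(self):
        cfg = SimulationConfig(seed=17, n_cohorts=1,
                               n_samples_per_cohort=400, n_tr_loci=5,
                               n_snv_loci=5)
        e = 0.05
        caller, truth, _ = simulate_truthset(cfg, error_rate=e)
        _, agg = concordance(caller, truth)
        n = agg["n_calls"]
        se = np.sqrt(e * (1 - e) / n)
        assert agg["strict_concordance"] == pytest.approx(1 - e, abs=4 * se)
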