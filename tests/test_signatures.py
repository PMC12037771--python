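import numpy as np
import pandas as pd
import pytest

from vttml.exceptions import ValidationError
from vttml.signatures import (GeneSignature, build_nax_signatures,
                              gene_inclusion_filter, km_median, list_signatures,
                              load_signature, logrank_test, quartile_stratify,
                              signature_score, stratify_survival)


class TestGeneInclusionFilter:
    def test_hand_enumerated_toy_matrix(self):
        counts = pd.DataFrame(
            {
                "S1": [100, 10, 0, 11, 5],
                "S2": [0, 9, 0, 12, 5],
                "S3": [50, 8, 0, 0, 5],
                "S4": [80, 10, 3, 13, 5],
            },
            index=["keep_high", "max_exactly_10", "mostly_zero",
                   "keep_with_one_zero", "max_below_10"],
        )
        kept = set(gene_inclusion_filter(counts))
        # keep_high: max 100 > 10, 3/4 nonzero > 1/2    -> kept
        # max_exactly_10: max == 10, strict             -> excluded
        # mostly_zero: nonzero in 1/4                   -> excluded
        # keep_with_one_zero: max 13, 3/4 nonzero       -> kept
        # max_below_10: max 5                           -> excluded
        assert kept == {"keep_high", "keep_with_one_zero"}

    def test_half_nonzero_is_excluded(self):
        counts = pd.DataFrame([[20, 30, 0, 0]], index=["g"],
                              columns=list("ABCD"))
        assert len(gene_inclusion_filter(counts)) == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            gene_inclusion_filter(pd.DataFrame([[-1, 2]], index=["g"]))


class TestBuildSignatures:
    def de(self, rows):
        return pd.DataFrame(rows, columns=["gene", "lfc", "padj"]).set_index("gene")

    def test_strict_boundaries(self):
        de = self.de([("exactly2", 2.0, 0.001), ("up", 2.5, 0.001),
                      ("down", -2.5, 0.001), ("minus2", -2.0, 0.001),
                      ("unadjusted", 3.0, 0.2)])
        resp, nonresp = build_nax_signatures(de)
        assert resp.genes == ["up"]
        assert nonresp.genes == ["down"]

    def test_planted_truth_recovered(self, small_cohort):
        truth = small_cohort.de_truth
        lfc = pd.Series(0.0, index=small_cohort.expression.index)
        lfc[truth["up"]] = small_cohort.spec.de_lfc
        lfc[truth["down"]] = -small_cohort.spec.de_lfc
        padj = pd.Series(0.5, index=lfc.index)
        padj[truth["up"] + truth["down"]] = 0.001
        de = pd.DataFrame({"lfc": lfc, "padj": padj})
        resp, nonresp = build_nax_signatures(de)
        assert set(resp.genes) == set(truth["up"])
        assert set(nonresp.genes) == set(truth["down"])

    def test_empty_direction_rejected(self):
        de = self.de([("up", 3.0, 0.001)])
        with pytest.raises(ValidationError, match="non-response"):
            build_nax_signatures(de)


class TestSignatureScore:
    def test_hand_computed_z_means(self):
        expr = pd.DataFrame({"A": [1.0, 10.0], "B": [2.0, 20.0],
                             "C": [3.0, 60.0]}, index=["g1", "g2"]).astype(float)
        sig = GeneSignature("toy", ["g1", "g2"])
        scores = signature_score(expr, sig)
        # g1: mean 2, sd 1 -> z = [-1, 0, 1]
        # g2: mean 30, sd ~26.458 -> z = [-0.7559, -0.3780, 1.1339]
        z2 = (np.array([10, 20, 60]) - 30) / np.std([10, 20, 60], ddof=1)
        expected = (np.array([-1.0, 0.0, 1.0]) + z2) / 2
        np.testing.assert_allclose(scores.to_numpy(), expected, atol=1e-12)

    def test_patient_at_cohort_mean_scores_zero(self):
        expr = pd.DataFrame({"A": [4.0], "B": [5.0], "C": [6.0]}, index=["g"])
        scores = signature_score(expr, GeneSignature("one", ["g"]))
        assert scores["B"] == pytest.approx(0.0)

    def test_scores_sum_to_zero(self, small_cohort):
        expr = np.log1p(small_cohort.expression).astype(float)
        sig = GeneSignature("some", list(expr.index[:15]))
        assert signature_score(expr, sig).sum() == pytest.approx(0.0, abs=1e-9)

    def test_affine_invariance_per_gene(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(5, 8)),
                            index=[f"g{i}" for i in range(5)])
        sig = GeneSignature("all", list(expr.index))
        base = signature_score(expr, sig)
        scaled = expr.mul(pd.Series([2.0, 5.0, 0.5, 9.0, 3.0], index=expr.index),
                          axis=0).add(pd.Series([1, -4, 2, 0, 7], index=expr.index),
                                      axis=0)
        np.testing.assert_allclose(base, signature_score(scaled, sig), atol=1e-9)

    def test_absent_genes_dropped_with_warning(self, caplog):
        expr = pd.DataFrame({"A": [1.0, 2.0], "B": [2.0, 1.0]}, index=["g1", "g2"])
        scores = signature_score(expr, GeneSignature("s", ["g1", "nope"]))
        assert len(scores) == 2

    def test_no_genes_present_rejected(self):
        expr = pd.DataFrame({"A": [1.0], "B": [2.0]}, index=["g1"])
        with pytest.raises(ValidationError):
            signature_score(expr, GeneSignature("s", ["absent"]))


def test_signature_registry_ships_named_panels():
    names = list_signatures()
    assert {"javelin_angio", "javelin_immuno", "immotion_angio",
            "immotion_immuno", "naxiva_angio", "naxiva_immuno"} <= set(names)
    assert len(load_signature("javelin_angio").genes) == 26
    assert "PGF" in load_signature("naxiva_angio").genes


class TestQuartileStratify:
    def test_anticorrelated_scores_give_two_per_stratum(self):
        ids = list("ABCDEFGH")
        resp = pd.Series(np.arange(8.0), index=ids)
        nonresp = pd.Series(np.arange(8.0)[::-1], index=ids)
        hi, lo = quartile_stratify(resp, nonresp)
        # Q3 of 0..7 = 5.25, Q1 = 1.75 -> top quartile {6,7}, bottom {0,1}
        assert set(hi) == {"G", "H"}
        assert set(lo) == {"A", "B"}

    def test_disjoint_strata(self):
        rng = np.random.default_rng(1)
        ids = [f"p{i}" for i in range(40)]
        resp = pd.Series(rng.normal(size=40), index=ids)
        nonresp = pd.Series(rng.normal(size=40), index=ids)
        hi, lo = quartile_stratify(resp, nonresp)
        assert not set(hi) & set(lo)
        assert len(hi) <= 10 and len(lo) <= 10

    def test_too_few_patients_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            quartile_stratify(s, s)


class TestKmMedian:
    def test_no_censoring_product_limit(self):
        surv = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 1, 1]})
        # S(2) = 0.5 -> earliest time with S <= 0.5 is 2
        assert km_median(surv) == 2.0

    def test_all_censored_undefined(self):
        surv = pd.DataFrame({"time": [5, 6], "event": [0, 0]})
        assert km_median(surv) is None

    def test_single_event(self):
        surv = pd.DataFrame({"time": [3.5], "event": [1]})
        assert km_median(surv) == 3.5

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            km_median(pd.DataFrame({"time": [-1.0], "event": [1]}))


def logrank_oracle(time_a, event_a, time_b, event_b):
    """Independent O/E/V bookkeeping over distinct event times."""
    times = np.concatenate([time_a, time_b])
    events = np.concatenate([event_a, event_b])
    group = np.concatenate([np.zeros(len(time_a)), np.ones(len(time_b))])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        surv = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 0]})
        stat, p = logrank_test(surv, surv.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_bookkeeping_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            ta = rng.exponential(10, size=12)
            tb = rng.exponential(4, size=10)
            ea = (rng.random(12) < 0.8).astype(int)
            eb = (rng.random(10) < 0.8).astype(int)
            a = pd.DataFrame({"time": ta, "event": ea})
            b = pd.DataFrame({"time": tb, "event": eb})
            stat, _ = logrank_test(a, b)
            assert stat == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-6)

    def test_symmetric_in_group_order(self):
        a = pd.DataFrame({"time": [1, 4, 6], "event": [1, 1, 0]})
        b = pd.DataFrame({"time": [2, 3, 9], "event": [1, 0, 1]})
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])

    def test_no_events_rejected(self):
        surv = pd.DataFrame({"time": [1, 2], "event": [0, 0]})
        with pytest.raises(ValidationError):
            logrank_test(surv, surv.copy())


def test_stratified_survival_end_to_end(small_cohort):
    rng = np.random.default_rng(5)
    ids = [f"x{i}" for i in range(60)]
    quality = pd.Series(rng.normal(size=60), index=ids)
    resp = quality + rng.normal(0, 0.3, 60)
    nonresp = -quality + rng.normal(0, 0.3, 60)
    from vttml.cohort import CohortSpec, generate_survival
    spec = CohortSpec(surv_hazard_ratio=6.0, censoring_rate=0.01, seed=1)
    surv = generate_survival(spec, pd.Series(quality < 0, index=ids),
                             np.random.default_rng(7))
    surv.insert(0, "pid", ids)
    surv = surv.drop(columns="patient_id").rename(columns={"pid": "patient_id"})
    res = stratify_survival(pd.Series(resp, index=ids),
                            pd.Series(nonresp, index=ids), surv)
    assert res.extras["n_hi"] > 0 and res.extras["n_lo"] > 0
    assert res.logrank_p is not None
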