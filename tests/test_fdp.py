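import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decoylink import (
    FDPEstimate,
    RecordTable,
    ScoredPairs,
    aggregate,
    augment_file,
    check_conditions,
    count_decoy_links,
    estimate_fdp,
    estimate_fdp_augmented,
    prob_fdp,
    run_procedure,
    tune_threshold,
)
from decoylink.fdp import CAPPED_MEAN, MEDIAN, TRUNCATED_MEAN, FDPCurve


def b_table(n, block=None):
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        {
            "v1": rng.integers(0, 6, n),
            "v2": rng.integers(0, 12, n),
            "record_id": [f"B{i}" for i in range(n)],
            "source": "B",
        }
    )
    if block is not None:
        df["block"] = block
    return RecordTable(df, ["v1", "v2"])


class TestAugment:
    def test_decoy_count_arithmetic(self):
        aug = augment_file(b_table(1000), alpha=0.10, seed=1)
        assert aug.n == 1100
        assert aug.is_synthetic.sum() == 100

    def test_zero_decoys_rejected(self):
        with pytest.raises(ValueError, match="synthetic set empty"):
            augment_file(b_table(4), alpha=0.01, seed=1)

    def test_alpha_range_enforced(self):
        for alpha in (0, -0.1, 0.21):
            with pytest.raises(ValueError, match="alpha"):
                augment_file(b_table(100), alpha=alpha, seed=1)

    def test_blocked_budget_split_per_block(self):
        B = b_table(1000, block=["north"] * 600 + ["south"] * 400)
        aug = augment_file(B, alpha=0.10, seed=1, block_on="block")
        synth = aug.data[aug.is_synthetic]
        assert dict(synth["block"].value_counts()) == {"north": 60, "south": 40}

    def test_same_seed_reproducible(self):
        a1 = augment_file(b_table(200), alpha=0.1, seed=9)
        a2 = augment_file(b_table(200), alpha=0.1, seed=9)
        pd.testing.assert_frame_equal(a1.data, a2.data)


class TestCounts:
    def test_empty_link_set(self):
        assert count_decoy_links(np.empty((0, 2), int), np.zeros(5, bool)) == (0, 0)

    def test_counting_split(self):
        prov = np.array([False, False, True, True, False])
        D = np.array([[0, 0], [1, 1], [2, 4], [3, 2], [4, 3]])
        assert count_decoy_links(D, prov) == (2, 3)

    def test_counts_match_loop_oracle(self, rng):
        prov = rng.random(30) < 0.3
        D = np.column_stack([rng.permutation(50)[:20], rng.permutation(30)[:20]])
        fp, nr = count_decoy_links(D, prov)
        fp_loop = sum(1 for _, j in D if prov[j])
        assert (fp, nr) == (fp_loop, len(D) - fp_loop)
        assert fp + nr == len(D)

    def test_unknown_j_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            count_decoy_links(np.array([[0, 7]]), np.zeros(5, bool))


class TestEstimators:
    def test_decoy_estimator_substitution(self):
        assert estimate_fdp(5, 200, 1000, 100) == pytest.approx(0.25)
        assert estimate_fdp(0, 123, 1000, 100) == 0.0
        est = FDPEstimate.from_counts(0.5, 30, 100, 1000, 100)
        assert est.fdp_hat == pytest.approx(3.0)
        assert est.exceeds_one

    def test_zero_links_conventions(self):
        assert estimate_fdp(0, 0, 1000, 100) == 0.0
        assert math.isinf(estimate_fdp(2, 0, 1000, 100))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_fdp(-1, 5, 100, 10)
        with pytest.raises(ValueError):
            estimate_fdp_augmented(1, 5, 100, 0)

    def test_augmented_variant_substitution(self):
        assert estimate_fdp_augmented(5, 205, 1000, 100) == pytest.approx(5 * 11 / 205)
        assert estimate_fdp_augmented(0, 50, 1000, 100) == 0.0

    def test_estimators_match_loop_oracle(self, rng):
        for _ in range(25):
            fp = int(rng.integers(0, 20))
            nr = int(rng.integers(1, 500))
            nb = int(rng.integers(100, 2000))
            ns = int(rng.integers(1, nb // 5 + 2))
            assert estimate_fdp(fp, nr, nb, ns) == pytest.approx(
                (fp * nb / ns) / nr, abs=1e-12
            )
            assert estimate_fdp_augmented(fp, nr + fp, nb, ns) == pytest.approx(
                fp * (1 + nb / ns) / (nr + fp), abs=1e-12
            )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        fp=st.integers(0, 50),
        nr=st.integers(1, 1000),
        nb=st.integers(10, 5000),
        ns=st.integers(1, 500),
        c=st.integers(1, 20),
    )
    def test_scale_equivariance(self, fp, nr, nb, ns, c):
        assert estimate_fdp(fp * c, nr, nb, ns * c) == pytest.approx(
            estimate_fdp(fp, nr, nb, ns)
        )


class TestProbFDP:
    def test_substitution(self):
        assert prob_fdp(np.array([0.8, 0.6]), 0.5) == pytest.approx(0.3)

    def test_perfect_scores_give_zero(self):
        assert prob_fdp(np.ones(10), 0.5) == 0.0
        assert prob_fdp(np.array([0.1, 0.2]), 0.5) == 0.0  # nothing retained

    def test_matches_loop_oracle(self, rng):
        d = rng.random(100)
        xi = 0.5
        kept = [x for x in d if x > xi]
        expect = sum(1 - x for x in kept) / len(kept)
        assert prob_fdp(d, xi) == pytest.approx(expect, abs=1e-12)


class TestConditions:
    def test_bias_flag_on_exceeding_one(self):
        est = FDPEstimate.from_counts(0.5, 30, 100, 1000, 100)
        diag = check_conditions(est)
        assert diag["exceeds_one"] and not diag["proportion_inequality_ok"]

    def test_exact_proportions_give_zero_difference(self):
        est = FDPEstimate.from_counts(0.5, 2, 200, 1000, 100)
        diag = check_conditions(est, n_A=500, fp_real=20)
        assert diag["condition_diff"] == pytest.approx(0.0)

    def test_difference_matches_recount(self):
        est = FDPEstimate.from_counts(0.5, 3, 150, 1000, 100)
        diag = check_conditions(est, n_A=400, fp_real=17)
        expect = 3 / (400 * 100) - 17 / (400 * 1000)
        assert diag["condition_diff"] == pytest.approx(expect)
        assert diag["condition_magnitude"] == math.floor(math.log10(abs(expect)))


class ScriptedLinker:
    """Links a fixed number of real and decoy pairs with high scores,
    constructed so that FPsynth/Nsynth = FP/NB exactly."""

    def __init__(self, tp, fp):
        self.tp, self.fp = tp, fp

    def __call__(self, A, B_aug, variables=None, block_on=None, seed=0):
        synth_j = np.flatnonzero(B_aug.is_synthetic)
        real_j = np.flatnonzero(~B_aug.is_synthetic)
        n_b, n_s = len(real_j), len(synth_j)
        fp_synth = round(self.fp * n_s / n_b)
        n_real = self.tp + self.fp
        j = np.r_[real_j[:n_real], synth_j[:fp_synth]]
        i = np.arange(len(j))
        return ScoredPairs(
            i=i,
            j=j,
            score=np.full(len(j), 0.99),
            is_synthetic_j=B_aug.is_synthetic[j],
        )


class TestProcedure:
    def test_scripted_linker_recovers_designed_fdp_exactly(self):
        B = b_table(1000)
        A = RecordTable(
            B.data.head(200).assign(source="A", record_id=[f"A{i}" for i in range(200)]),
            B.variables,
        )
        curve = run_procedure(
            A, B, ScriptedLinker(tp=80, fp=20), alpha=0.10,
            xi_grid=[0.5, 0.7], repetitions=3, seed=5,
        )
        for rep in curve.replicates:
            for est in rep:
                assert est.fdp_hat == pytest.approx(20 / 100)  # FP/(TP+FP)

    def test_same_master_seed_identical_curves(self):
        B = b_table(300)
        A = RecordTable(
            B.data.head(60).assign(source="A", record_id=[f"A{i}" for i in range(60)]),
            B.variables,
        )
        link = ScriptedLinker(tp=30, fp=10)
        c1 = run_procedure(A, B, link, xi_grid=[0.5], repetitions=2, seed=11)
        c2 = run_procedure(A, B, link, xi_grid=[0.5], repetitions=2, seed=11)
        pd.testing.assert_frame_equal(c1.to_frame(), c2.to_frame())

    def test_single_repetition_single_threshold(self):
        B = b_table(300)
        A = RecordTable(
            B.data.head(60).assign(source="A", record_id=[f"A{i}" for i in range(60)]),
            B.variables,
        )
        curve = run_procedure(A, B, ScriptedLinker(20, 5), xi_grid=[0.5], repetitions=1, seed=1)
        assert curve.repetitions == 1 and len(curve.replicates[0]) == 1

    def test_invalid_grid_rejected(self):
        B = b_table(100)
        with pytest.raises(ValueError, match="grid"):
            run_procedure(B, B, ScriptedLinker(1, 1), xi_grid=[0.4], repetitions=1, seed=0)


def curve_from(values_per_xi: dict) -> FDPCurve:
    xi_grid = list(values_per_xi)
    n_rep = len(next(iter(values_per_xi.values())))
    reps = []
    for r in range(n_rep):
        reps.append(
            [
                FDPEstimate(
                    xi=xi, fp_synth=0, n_real_linked=100, n_all_linked=100,
                    n_B=1000, n_synth=100, fdp_hat=values_per_xi[xi][r],
                    fdp_hat_synth=0.0,
                )
                for xi in xi_grid
            ]
        )
    return FDPCurve(xi_grid=xi_grid, replicates=reps, n_B=1000, alpha=0.1, seed=0)


class TestAggregate:
    def test_three_methods_on_known_replicates(self):
        curve = curve_from({0.5: [0.2, 0.3, 1.4]})
        assert aggregate(curve, TRUNCATED_MEAN)["estimate"][0] == pytest.approx(0.25)
        assert aggregate(curve, CAPPED_MEAN)["estimate"][0] == pytest.approx(0.5)
        assert aggregate(curve, MEDIAN)["estimate"][0] == pytest.approx(0.3)

    def test_single_replicate_se_zero(self):
        agg = aggregate(curve_from({0.5: [0.4]}), CAPPED_MEAN)
        assert agg["estimate"][0] == pytest.approx(0.4)
        assert agg["se"][0] == 0.0

    def test_all_exceeding_one_errors_for_truncated_mean(self):
        curve = curve_from({0.5: [1.2, 1.5]})
        with pytest.raises(ValueError, match="exceed one"):
            aggregate(curve, TRUNCATED_MEAN)
        assert aggregate(curve, CAPPED_MEAN)["estimate"][0] == pytest.approx(1.0)

    def test_methods_bounded_by_replicate_range(self, rng):
        vals = list(np.round(rng.random(10), 3))
        curve = curve_from({0.5: vals})
        for method in (TRUNCATED_MEAN, CAPPED_MEAN, MEDIAN):
            est = aggregate(curve, method)["estimate"][0]
            assert min(vals) <= est <= max(vals)


class TestTune:
    def make_agg(self):
        return pd.DataFrame(
            {
                "xi": [0.5, 0.7, 0.9],
                "estimate": [0.40, 0.12, 0.08],
                "se": [0.0] * 3,
                "n_used": [10] * 3,
                "n_exceeding_one": [0] * 3,
                "mean_links": [500.0, 300.0, 120.0],
            }
        )

    def test_smallest_threshold_meeting_target(self):
        res = tune_threshold(self.make_agg(), 0.10)
        assert res.achieved and res.xi == 0.9 and res.links_retained == 120.0

    def test_loose_target_keeps_loosest_threshold(self):
        assert tune_threshold(self.make_agg(), 0.5).xi == 0.5

    def test_unreachable_target_flagged(self):
        res = tune_threshold(self.make_agg(), 0.01)
        assert not res.achieved and res.xi is None
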