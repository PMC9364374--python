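import math

import numpy as np
import pandas as pd
import pytest

from shadowfold.scoring_stats import (aggregate_report, auc_shadow, f1_score,
                                      minmax_normalize, paired_ttest,
                                      score_pairs_slippage)
from shadowfold.synthetic_families import sample_structure


def _bruteforce_slippage(predicted, reference, slip=1):
    """Oracle: match via explicitly expanded displacement sets."""
    def expand(pair):
        i, j = pair
        out = {(i, j)}
        if slip:
            out |= {(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)}
        return out

    mp = sum(bool(expand(p) & set(reference)) for p in predicted)
    mr = sum(bool(expand(p) & set(predicted)) for p in reference)
    return mp, mr


class TestSlippageScorer:
    def test_identity(self):
        sc = score_pairs_slippage({(1, 10), (2, 9)}, {(1, 10), (2, 9)})
        assert (sc.ppv, sc.sensitivity, sc.f1) == (1.0, 1.0, 1.0)

    def test_displaced_partner_counts(self):
        sc = score_pairs_slippage({(1, 9)}, {(1, 10), (2, 9)})
        assert sc.ppv == 1.0
        assert sc.sensitivity == 1.0  # both ref pairs within one displacement
        assert sc.f1 == 1.0

    def test_half_sensitivity(self):
        sc = score_pairs_slippage({(1, 10)}, {(1, 10), (20, 30)})
        assert sc.ppv == 1.0
        assert sc.sensitivity == 0.5
        assert sc.f1 == pytest.approx(2 / 3)

    def test_empty_prediction_nonempty_reference(self):
        sc = score_pairs_slippage(set(), {(1, 10)})
        assert sc.f1 == 0.0

    def test_both_empty_is_perfect(self):
        sc = score_pairs_slippage(set(), set())
        assert sc.f1 == 1.0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match="out of range"):
            score_pairs_slippage({(1, 99)}, set(), length=50)

    def test_matches_bruteforce_on_random_structures(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(20, 60))
            a = sample_structure(n, int(rng.integers(2**31)))
            b = sample_structure(n, int(rng.integers(2**31)))
            sc = score_pairs_slippage(a, b)
            mp, mr = _bruteforce_slippage(a, b)
            assert (sc.matched_pred, sc.matched_ref) == (mp, mr)

    def test_zero_slippage_is_set_intersection(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(20, 60))
            a = sample_structure(n, int(rng.integers(2**31)))
            b = sample_structure(n, int(rng.integers(2**31)))
            sc = score_pairs_slippage(a, b, slippage=0)
            assert sc.matched_pred == len(set(a) & set(b)) == sc.matched_ref


class TestF1:
    @pytest.mark.parametrize("p,s,expected",
                             [(1, 1, 1.0), (0, 0.7, 0.0), (1, 0.5, 2 / 3)])
    def test_values(self, p, s, expected):
        assert f1_score(p, s) == pytest.approx(expected)

    def test_bounded_by_max_component(self):
        rng = np.random.default_rng(1)
        for p, s in rng.random((100, 2)):
            assert 0 <= f1_score(p, s) <= max(p, s) + 1e-12


class TestAuc:
    def test_perfect_separation(self):
        sh = np.array([1, 0, 1, 0])
        assert auc_shadow(sh.astype(float), sh).auc == 1.0

    def test_constant_prediction_is_half(self):
        assert auc_shadow([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == 0.5

    def test_enumerated_example(self):
        roc = auc_shadow([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert roc.auc == 0.75  # 3 of 4 pairwise comparisons won

    def test_degenerate_shadow_is_undefined(self):
        assert not auc_shadow([0.2, 0.9], [1, 1]).defined

    def test_equals_exhaustive_pairwise_fraction(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            sh = (rng.random(n) < 0.5).astype(int)
            if sh.sum() in (0, n):
                continue
            y = np.round(rng.random(n), 2)  # coarse grid to exercise ties
            roc = auc_shadow(y, sh)
            wins = ties = 0
            for i in np.flatnonzero(sh == 1):
                for j in np.flatnonzero(sh == 0):
                    wins += y[i] > y[j]
                    ties += y[i] == y[j]
            expected = (wins + 0.5 * ties) / (sh.sum() * (n - sh.sum()))
            assert roc.auc == pytest.approx(expected)


class TestPairedTtest:
    def test_identical_vectors(self):
        assert paired_ttest([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_symmetric_differences(self):
        t, p = paired_ttest([1, 0], [0, 1])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_example(self):
        t, p = paired_ttest([1, 2, 3], [0, 0, 0])
        assert t == pytest.approx(2 * math.sqrt(3))
        assert p == pytest.approx(0.0742, abs=1e-3)

    def test_zero_variance_nonzero_mean_is_degenerate(self):
        t, p = paired_ttest([1, 1, 1], [0, 0, 0])
        assert math.isinf(t) and t > 0
        assert p == 0.0


class TestMinmax:
    def test_basic(self):
        assert minmax_normalize([2, 4, 6]).tolist() == [0, 0.5, 1]

    def test_idempotent_on_unit_range(self):
        v = [0.0, 0.3, 1.0]
        assert minmax_normalize(v).tolist() == v

    def test_negative_values(self):
        assert minmax_normalize([-1, 0, 3]).tolist() == [0, 0.25, 1]

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize([1, 1, 1])


class TestAggregateReport:
    def test_family_fold_mean_row(self):
        fam_f1 = [0.46, 0.50, 0.65, 0.41, 0.48, 0.49, 0.48, 0.45, 0.54]
        df = pd.DataFrame({"family": [f"f{i}" for i in range(9)],
                           "f1": fam_f1})
        rep = aggregate_report(df)
        assert rep.loc["Mean", "f1"] == pytest.approx(0.50, abs=0.005)

    def test_single_family(self):
        df = pd.DataFrame({"family": ["a"] * 3, "f1": [0.2, 0.4, 0.6]})
        rep = aggregate_report(df)
        assert rep.loc["Mean", "f1"] == pytest.approx(0.4)

    def test_grand_mean_is_unweighted(self):
        df = pd.DataFrame({
            "family": ["big"] * 1000 + ["small"] * 10,
            "f1": [1.0] * 1000 + [0.0] * 10,
        })
        rep = aggregate_report(df)
        assert rep.loc["Mean", "f1"] == pytest.approx(0.5)

    def test_nan_metrics_excluded_with_counts(self):
        df = pd.DataFrame({"family": ["a", "a", "b"],
                           "auc": [0.8, np.nan, 0.6]})
        rep = aggregate_report(df)
        assert rep.loc["a", "auc"] == pytest.approx(0.8)
        assert rep.loc["a", "n_auc"] == 1
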