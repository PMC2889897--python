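"""Cross-cohort fold-quotient correlation and qPCR ddCt concordance."""
import numpy as np
import pandas as pd
import pytest

from mirblood.concordance import (
    FoldQuotientSet,
    ddct_fold_change,
    log_fold_correlation,
    per_set_fold_quotients,
    platform_correlation,
)
from mirblood.simulate import QpcrPanel


def _matrix(values, features):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return pd.DataFrame(
        values, index=features, columns=[f"s{j}" for j in range(values.shape[1])]
    )


def _fqset(quotients: dict, medians: dict, min_median=50.0, label="x"):
    idx = pd.Index(list(quotients))
    return FoldQuotientSet(
        label=label,
        quotients=pd.Series([quotients[f] for f in idx], index=idx),
        case_medians=pd.Series([medians[f] for f in idx], index=idx),
        min_median=min_median,
    )


class TestPerSetFoldQuotients:
    def test_identical_matrices_give_unit_quotients(self):
        m = _matrix(np.random.default_rng(0).uniform(10, 100, (4, 5)), list("abcd"))
        fq = per_set_fold_quotients(m, m)
        np.testing.assert_allclose(fq.quotients, 1.0)

    def test_mismatched_universe_rejected(self):
        a = _matrix([[1, 2]], ["x"])
        b = _matrix([[1, 2]], ["y"])
        with pytest.raises(ValueError, match="feature universe"):
            per_set_fold_quotients(a, b)

    def test_zero_control_median_dropped(self):
        case = _matrix([[10, 10], [20, 20]], ["a", "b"])
        control = _matrix([[0, 0], [10, 10]], ["a", "b"])
        fq = per_set_fold_quotients(case, control)
        assert list(fq.quotients.index) == ["b"]


class TestLogFoldCorrelation:
    def _pair(self, med_a, med_b, n=10, seed=0):
        """Two sets with matching quotients; per-feature medians as given."""
        rng = np.random.default_rng(seed)
        q = rng.uniform(0.3, 3.0, size=n)
        idx = [f"f{i}" for i in range(n)]
        a = _fqset(dict(zip(idx, q)), dict(zip(idx, med_a)))
        b = _fqset(dict(zip(idx, q * rng.uniform(0.9, 1.1, n))), dict(zip(idx, med_b)))
        return a, b

    def test_either_set_retention(self):
        # 40/60 retained (one arm reaches 50); 40/45 dropped
        a = _fqset({"keep": 2.0, "drop": 2.0, "x": 1.0, "y": 1.0, "z": 1.5},
                   {"keep": 40, "drop": 40, "x": 80, "y": 90, "z": 100})
        b = _fqset({"keep": 2.1, "drop": 2.1, "x": 1.0, "y": 1.1, "z": 1.4},
                   {"keep": 60, "drop": 45, "x": 80, "y": 90, "z": 100})
        # drop-feature removal changes the correlation inputs: check by
        # comparing against the correlation computed on the retained set only
        r = log_fold_correlation(a, b)
        kept = ["keep", "x", "y", "z"]
        expected = np.corrcoef(
            np.log([a.quotients[f] for f in kept]),
            np.log([b.quotients[f] for f in kept]),
        )[0, 1]
        assert r == pytest.approx(expected)

    def test_identical_sets_give_unit_correlation(self):
        a, _ = self._pair([100] * 10, [100] * 10)
        assert log_fold_correlation(a, a) == pytest.approx(1.0)

    def test_reciprocal_sets_anticorrelate(self):
        a, _ = self._pair([100] * 10, [100] * 10)
        b = FoldQuotientSet("recip", 1.0 / a.quotients, a.case_medians, a.min_median)
        assert log_fold_correlation(a, b) == pytest.approx(-1.0)

    def test_scale_invariance(self):
        a, b = self._pair([100] * 10, [100] * 10, seed=3)
        scaled = FoldQuotientSet("s", b.quotients * 7.3, b.case_medians, b.min_median)
        assert log_fold_correlation(a, scaled) == pytest.approx(
            log_fold_correlation(a, b)
        )

    def test_too_few_shared_features_rejected(self):
        a, b = self._pair([100] * 10, [10] * 10)
        b = FoldQuotientSet(b.label, b.quotients, b.case_medians * 0 + 10, 5000.0)
        a = FoldQuotientSet(a.label, a.quotients, a.case_medians * 0 + 10, 5000.0)
        with pytest.raises(ValueError, match="need >= 3"):
            log_fold_correlation(a, b)

    def test_synthetic_arms_concord(self):
        """Test and validation melanoma arms of the generator correlate on
        log fold quotients (>= 0.7 in >= 90% of 20 seeds)."""
        from mirblood import generate_cohort, preprocess
        from mirblood.config import SimulationConfig

        hits = 0
        for seed in range(20):
            probe, ann, _ = generate_cohort(SimulationConfig(seed=500 + seed))
            m = preprocess(probe)
            by = ann.set_index("sample_id")["group"]
            ctrl = m[by[by == "C"].index]
            a = per_set_fold_quotients(m[by[by == "M"].index], ctrl, label="test")
            b = per_set_fold_quotients(m[by[by == "N"].index], ctrl, label="validation")
            if log_fold_correlation(a, b) >= 0.7:
                hits += 1
        assert hits >= 18


class TestDdct:
    def _panel(self, ct_case, ct_ctrl, endo=20.0):
        n = len(ct_case)
        sample_ids = [f"c{i}" for i in range(n)] + [f"m{i}" for i in range(n)]
        ct = pd.DataFrame(
            {"mirX": list(ct_ctrl) + list(ct_case), "RNU48": [endo] * 2 * n},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        samples = pd.DataFrame(
            {"sample_id": sample_ids, "group": ["C"] * n + ["M"] * n}
        )
        return QpcrPanel(samples=samples, ct=ct)

    def test_equal_mean_dct_gives_fold_one(self):
        panel = self._panel([25.0, 26.0], [26.0, 25.0])
        assert ddct_fold_change(panel)["mirX"] == pytest.approx(1.0)

    def test_ddct_minus_one_gives_fold_two(self):
        panel = self._panel([24.0, 24.0], [25.0, 25.0])
        assert ddct_fold_change(panel)["mirX"] == pytest.approx(2.0)

    def test_ddct_plus_one_gives_fold_half(self):
        panel = self._panel([26.0, 26.0], [25.0, 25.0])
        assert ddct_fold_change(panel)["mirX"] == pytest.approx(0.5)

    def test_missing_ct_excluded_with_warning(self):
        panel = self._panel([25.0, np.nan], [25.0, 25.0])
        with pytest.warns(UserWarning, match="missing Ct"):
            folds = ddct_fold_change(panel)
        assert "mirX" not in folds.index

    def test_missing_control_ct_rejected(self):
        panel = self._panel([25.0, 25.0], [25.0, 25.0])
        panel.ct.loc[panel.ct.index[0], "RNU48"] = np.nan
        with pytest.raises(ValueError, match="endogenous-control"):
            ddct_fold_change(panel)


class TestPlatformCorrelation:
    def test_identical_vectors(self):
        x = pd.Series([0.5, 1.0, 2.0], index=list("abc"))
        assert platform_correlation(x, x) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        x = pd.Series([0.5, 1.0, 2.0], index=list("abc"))
        y = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            platform_correlation(x, y)

    def test_too_few_pairs_rejected(self):
        x = pd.Series([0.5, 1.0], index=list("ab"))
        with pytest.raises(ValueError, match="paired features"):
            platform_correlation(x, x)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(4)
        idx = [f"f{i}" for i in range(13)]
        x = pd.Series(rng.uniform(0.3, 3.0, 13), index=idx)
        y = pd.Series(x.to_numpy() * rng.uniform(0.8, 1.2, 13), index=idx)
        r = platform_correlation(x, y)
        xv, yv = x.to_numpy(), y.to_numpy()
        expected = ((xv - xv.mean()) * (yv - yv.mean())).sum() / np.sqrt(
            ((xv - xv.mean()) ** 2).sum() * ((yv - yv.mean()) ** 2).sum()
        )
        assert r == pytest.approx(expected, rel=1e-12)
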