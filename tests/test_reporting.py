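"""Forward selection, quadrants, membership-bin mortality and report tables."""

import numpy as np
import pytest

from phenotensor import (
    build_report,
    forward_select_phenotypes,
    mortality_by_membership_bin,
    phenotype_quadrants,
    prevalence,
    representative_phenotypes,
    read_phenotype_report,
    write_phenotype_report,
)
from phenotensor.decomposition import FactorModel, normalize_and_threshold
from phenotensor.errors import DegenerateLabelsError
from phenotensor.reporting import SelectionResult


def _simulated_selection(seed, n=500, p=10, informative=0, log_odds=2.0):
    rng = np.random.default_rng(seed)
    x = rng.random((n, p))
    logits = np.zeros(n)
    if informative is not None:
        logits = log_odds * (x[:, informative] - 0.5) * 4  # planted effect
    y = np.where(rng.random(n) < 1 / (1 + np.exp(-logits)), 1.0, -1.0)
    return x, y


class TestForwardSelection:
    def test_planted_informative_feature_enters_first(self):
        hits = 0
        for seed in range(10):
            x, y = _simulated_selection(seed, informative=3)
            sel = forward_select_phenotypes(x, y)
            if sel.order and sel.order[0] == 3:
                hits += 1
        assert hits >= 9

    def test_all_noise_selects_little(self):
        empties, sizes = 0, []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x = rng.random((300, 9))
            y = np.where(rng.random(300) < 0.5, 1.0, -1.0)
            sel = forward_select_phenotypes(x, y)
            sizes.append(len(sel.order))
            empties += not sel.order
        # entry guarded by p < 0.05: mostly empty, never more than a couple
        assert empties >= 4
        assert max(sizes) <= 3

    def test_perfect_separator_stays_finite(self):
        rng = np.random.default_rng(11)
        x = rng.random((200, 5))
        y = np.where(x[:, 3] > 0.5, 1.0, -1.0)
        sel = forward_select_phenotypes(x, y)
        assert sel.order[0] == 3
        assert np.isfinite(sel.coefficients[3])
        assert sel.ridge_fallback

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            forward_select_phenotypes(np.ones((4, 2)), np.ones(4))

    def test_logistic_stats_match_statsmodels(self):
        """Coefficients and Wald p-values agree with an independent maximum
        likelihood implementation on a well-conditioned instance."""
        import statsmodels.api as sm

        from phenotensor.reporting import _logistic_with_stats

        rng = np.random.default_rng(21)
        x = rng.random((300, 3))
        logits = 2.0 * x[:, 0] - 1.5 * x[:, 2]
        y = np.where(rng.random(300) < 1 / (1 + np.exp(-logits)), 1.0, -1.0)
        theta, p, dev, fallback = _logistic_with_stats(x, y)
        assert not fallback
        ref = sm.Logit((y == 1).astype(float), sm.add_constant(x, prepend=False)).fit(disp=0)
        np.testing.assert_allclose(theta, ref.params, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(p, ref.pvalues, rtol=1e-3, atol=1e-8)
        assert dev == pytest.approx(-2 * ref.llf, rel=1e-6)


class TestRepresentative:
    def test_threshold_cases(self):
        sel = SelectionResult(order=[3, 5, 6],
                              coefficients={3: 44.64, 5: -19.76, 6: 88.87},
                              p_values={3: 0.0, 5: 0.0, 6: 0.0}, intercept=0.0)
        assert representative_phenotypes(sel, 20) == [3, 6]
        assert representative_phenotypes(sel, 0) == [3, 5, 6]
        empty = SelectionResult(order=[], coefficients={}, p_values={}, intercept=0.0)
        assert representative_phenotypes(empty) == []


class TestQuadrants:
    def test_top_five_lambda_and_sign(self):
        lam = {i: 100.0 - i for i in range(7)}
        prev = {i: 50.0 for i in range(7)}
        coef = {i: (1.0 if i % 2 == 0 else -1.0) for i in range(7)}
        quads = phenotype_quadrants(lam, prev, coef)
        assert quads[0] == "common-high" and quads[1] == "common-low"
        assert quads[5] == "rare-low" and quads[6] == "rare-high"
        assert sum(q.startswith("common") for q in quads.values()) == 5

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        ids = list(range(8))
        lam = {i: float(rng.random()) for i in ids}
        prev = {i: float(rng.random() * 100) for i in ids}
        coef = {i: float(rng.normal()) for i in ids}
        base = phenotype_quadrants(lam, prev, coef)
        shuffled_ids = [ids[j] for j in rng.permutation(8)]
        again = phenotype_quadrants({i: lam[i] for i in shuffled_ids},
                                    {i: prev[i] for i in shuffled_ids},
                                    {i: coef[i] for i in shuffled_ids})
        assert base == again


class TestMortalityBins:
    def test_single_populated_bin(self):
        member = np.full(20, 0.05)
        y = np.array([1] * 10 + [-1] * 10)
        tab = mortality_by_membership_bin(member, y)
        assert tab.loc[0, "mortality"] == pytest.approx(0.5)
        assert tab.loc[1:, "mortality"].isna().all()

    def test_small_bins_are_empty(self):
        member = np.full(9, 0.55)
        y = np.ones(9)
        tab = mortality_by_membership_bin(member, y, min_count=10)
        assert tab["mortality"].isna().all()
        assert tab.loc[5, "count"] == 9

    def test_matches_bruteforce_binning(self):
        rng = np.random.default_rng(13)
        member = rng.random(200)
        y = np.where(rng.random(200) < 0.4, 1, -1)
        tab = mortality_by_membership_bin(member, y, min_count=1)
        assert tab["count"].sum() == 200
        for m in range(10):
            lo, hi = m * 0.1, (m + 1) * 0.1
            mask = (member >= lo) & (member < hi)
            if m == 9:
                mask |= member == 1.0
            assert tab.loc[m, "count"] == mask.sum()
            if mask.sum():
                assert tab.loc[m, "mortality"] == pytest.approx(np.mean(y[mask] == 1))


class TestPrevalence:
    def test_edges_and_hand_count(self):
        assert prevalence(np.zeros(10)) == 0.0
        assert prevalence(np.ones(10)) == 100.0
        rng = np.random.default_rng(14)
        col = rng.random(50) * (rng.random(50) < 0.3)
        assert prevalence(col) == pytest.approx(100.0 * np.count_nonzero(col) / 50)


class TestReportAssembly:
    def _fitted_model(self, seed=15, i=80, r=4):
        rng = np.random.default_rng(seed)
        m = FactorModel(A=rng.random((i, r)) * (rng.random((i, r)) < 0.7),
                        B=rng.random((6, r)), C=rng.random((7, r)), theta=np.zeros(r + 1))
        return normalize_and_threshold(m)

    def test_build_and_roundtrip(self, tmp_path):
        model = self._fitted_model()
        rng = np.random.default_rng(16)
        y = np.where(model.A_bar[:, 0] + 0.3 * rng.random(80) > 0.4, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        report = build_report(model, y, min_count=3)
        assert len(report.summary) == 4
        assert set(report.summary["quadrant"]) - {""} <= {
            "common-high", "common-low", "rare-high", "rare-low"}
        assert report.summary.loc[report.summary["representative"], "selected"].all()
        write_phenotype_report(report, tmp_path / "rep")
        back = read_phenotype_report(tmp_path / "rep")
        for col in ("lam", "prevalence", "coefficient", "p_value"):
            np.testing.assert_allclose(back.summary[col], report.summary[col],
                                       rtol=1e-12, atol=1e-300, equal_nan=True)
        np.testing.assert_allclose(back.members["membership"], report.members["membership"], rtol=1e-12)
        np.testing.assert_allclose(back.bins["mortality"], report.bins["mortality"],
                                   rtol=1e-12, equal_nan=True)

    def test_empty_selection_report(self, tmp_path):
        model = self._fitted_model(seed=17)
        rng = np.random.default_rng(18)
        y = np.where(rng.random(80) < 0.5, 1, -1)  # noise outcome: likely nothing selected
        report = build_report(model, y)
        assert (~report.summary["selected"]).sum() >= 1
        write_phenotype_report(report, tmp_path / "rep")
        back = read_phenotype_report(tmp_path / "rep")
        assert len(back.summary) == len(report.summary)
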