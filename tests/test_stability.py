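import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from selstab import (SelectionEnsemble, bootstrap_plan, fit_model, msf,
                     pairwise_inclusion, rcb, rmsdr, shrinkage_factor,
                     stability_report, subsample_plan, top_models, vif)
from selstab.models import FittedModel
from selstab.stability import vif_all

from conftest import make_linear_dataset


def mk_ens(coefficients, selected=None, columns=None):
    """Hand-built ensemble with single-column terms named like columns."""
    coefficients = np.asarray(coefficients, dtype=float)
    if selected is None:
        selected = coefficients != 0.0
    selected = np.asarray(selected, dtype=bool)
    B, p = coefficients.shape
    if columns is None:
        columns = tuple(chr(ord("a") + j) for j in range(p))
    return SelectionEnsemble(plan=bootstrap_plan(B=B, seed=0),
                             term_names=tuple(columns),
                             columns=tuple(columns),
                             coefficients=coefficients, selected=selected,
                             n_failed=0, data=None)


def mk_global(params, bse=None, columns=None):
    params = np.asarray(params, dtype=float)
    p = len(params)
    if bse is None:
        bse = np.ones(p)
    if columns is None:
        columns = tuple(chr(ord("a") + j) for j in range(p))
    return FittedModel(family="linear", columns=tuple(columns),
                       term_map={c: np.array([j])
                                 for j, c in enumerate(columns)},
                       params=params, bse=np.asarray(bse, float),
                       cov=np.diag(np.asarray(bse, float) ** 2),
                       loglik=0.0, aic=0.0, nobs=100, df_resid=90)


class TestVifMsf:
    def test_vif_is_selection_fraction(self):
        ens = mk_ens(np.array([[1.0], [0.0], [2.0], [3.0]]))
        assert vif(ens, "a") == pytest.approx(0.75)

    def test_never_selected_vif_zero(self):
        ens = mk_ens(np.zeros((5, 1)))
        assert vif(ens, "a") == 0.0

    def test_msf_counts_exact_sets(self):
        # resample selections: {a,b}, {a,b}, {a}, {b}
        coefs = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        ens = mk_ens(coefs)
        assert msf(ens, {"a", "b"}) == pytest.approx(0.5)
        assert msf(ens, {"a"}) == pytest.approx(0.25)
        assert msf(ens, set()) == 0.0

    def test_single_model_everywhere(self):
        ens = mk_ens(np.ones((6, 2)))
        assert msf(ens, {"a", "b"}) == 1.0
        assert msf(ens, {"a"}) == 0.0

    def test_top_models_ranked_with_tie_by_first_occurrence(self):
        coefs = np.array([[0.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 1.0],
                          [0.0, 1.0]])
        tm = top_models(mk_ens(coefs))
        assert tm["frequency"].sum() == pytest.approx(1.0)
        assert list(tm["model"])[:2] == ["b", "a + b"]


class TestRcbSf:
    def test_rcb_worked_example(self):
        # beta~ = 2; resample estimates 2.5, 2.5, 0, 0 -> VIF 0.5,
        # RCB = 5/(2 * 0.5 * 4) - 1 = 0.25
        ens = mk_ens(np.array([[2.5], [2.5], [0.0], [0.0]]))
        g = mk_global([2.0])
        r = rcb(ens, g, "a")
        assert r.vif == pytest.approx(0.5)
        assert r.value == pytest.approx(0.25)

    def test_rcb_zero_when_resamples_reproduce_global(self):
        ens = mk_ens(np.array([[1.3], [1.3], [0.0], [1.3]]))
        r = rcb(ens, mk_global([1.3]), "a")
        assert r.value == pytest.approx(0.0, abs=1e-14)

    def test_rcb_undefined_when_never_selected(self):
        ens = mk_ens(np.zeros((4, 1)))
        r = rcb(ens, mk_global([1.0]), "a")
        assert np.isnan(r.value)
        assert "selected" in r.note

    @pytest.mark.parametrize("seed", range(8))
    def test_dual_formula_identity(self, seed):
        # Sum_b beta^b/(beta~ VIF B) - 1 == conditional mean ratio - 1,
        # exactly (asserted internally to 1e-12)
        rng = np.random.default_rng(seed)
        B, p = 200, 4
        sel = rng.random((B, p)) < rng.uniform(0.2, 0.9, p)
        sel[0] = True
        coefs = rng.normal(1.0, 0.5, (B, p)) * sel
        ens = mk_ens(coefs, selected=sel)
        g = mk_global(rng.uniform(0.5, 2.0, p))
        for c in ens.columns:
            r = rcb(ens, g, c)
            manual = coefs[:, ens.columns.index(c)]
            manual = manual[sel[:, ens.columns.index(c)]]
            expected = manual.mean() / g.coef(c) - 1.0
            assert r.value == pytest.approx(expected, abs=1e-12)

    def test_shrinkage_factor_reference_pairs(self):
        # RCB x100 = 9.984 -> SF 0.909; 44.691 -> 0.691
        assert shrinkage_factor(0.09984)[0] == pytest.approx(0.909, abs=5e-4)
        assert shrinkage_factor(0.44691)[0] == pytest.approx(0.691, abs=5e-4)
        assert shrinkage_factor(0.0) == (1.0, None)

    def test_shrinkage_factor_delta_method_se(self):
        sf, se = shrinkage_factor(0.25, se_rcb=0.1)
        assert sf == pytest.approx(0.8)
        assert se == pytest.approx(0.1 * 0.8 ** 2)

    def test_shrinkage_factor_undefined_below_minus_one(self):
        with pytest.raises(ValueError):
            shrinkage_factor(-1.2)


class TestRmsdr:
    def test_zero_when_resamples_equal_global(self):
        ens = mk_ens(np.full((5, 1), 1.7))
        assert rmsdr(ens, mk_global([1.7], [0.4]), "a") == 0.0

    def test_worked_example(self):
        # beta~=1, se~=0.5, estimates (1.5, 0.5):
        # sqrt((0.25+0.25)/2)/0.5 = 1
        ens = mk_ens(np.array([[1.5], [0.5]]))
        assert rmsdr(ens, mk_global([1.0], [0.5]), "a") == pytest.approx(1.0)

    def test_nonselection_counts_as_full_deviation(self):
        ens = mk_ens(np.array([[1.0], [0.0]]))
        # deviations 0 and beta~ -> sqrt(beta~^2/2)/se
        assert rmsdr(ens, mk_global([1.0], [0.5]), "a") == pytest.approx(
            np.sqrt(0.5) / 0.5)


class TestPairwise:
    def test_always_together_is_one(self):
        ens = mk_ens(np.ones((6, 2)))
        pw = pairwise_inclusion(ens)
        assert pw.loc["a", "b"] == 1.0

    def test_disjoint_is_zero_and_diagonal_is_vif(self):
        coefs = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        pw = pairwise_inclusion(mk_ens(coefs))
        assert pw.loc["a", "b"] == 0.0
        assert pw.loc["a", "a"] == pytest.approx(2 / 3)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds_and_partition_properties(self, seed):
        """On any ensemble: pairwise(i,j) <= min(VIF_i, VIF_j); MSFs over
        distinct models partition to 1; MSF <= VIF_in and <= 1 - VIF_out."""
        rng = np.random.default_rng(seed)
        B, p = rng.integers(2, 40), rng.integers(1, 5)
        sel = rng.random((B, p)) < rng.random(p)
        ens = mk_ens(rng.normal(size=(B, p)) * sel, selected=sel)
        pw = pairwise_inclusion(ens).to_numpy()
        v = ens.selected.mean(axis=0)
        for i in range(p):
            for j in range(p):
                assert pw[i, j] <= min(v[i], v[j]) + 1e-12
        tm = top_models(ens)
        assert tm["frequency"].sum() == pytest.approx(1.0)
        for _, row in tm.iterrows():
            terms = () if row["model"] == "(empty)" else tuple(
                row["model"].split(" + "))
            f = row["frequency"]
            for ti, t in enumerate(ens.term_names):
                bound = v[ti] if t in terms else 1.0 - v[ti]
                assert f <= bound + 1e-12


class TestReport:
    def make_report(self, d, **kw):
        kw.setdefault("inclusion_plan", subsample_plan(0.5, B=80, seed=5))
        kw.setdefault("bias_plan", bootstrap_plan(B=80, seed=6))
        return stability_report(d, **kw)

    def test_invariants_and_layout(self, toy_linear):
        rep = self.make_report(toy_linear)
        rep.validate()
        assert list(rep.table.columns[:1]) == ["term"]
        assert rep.table["vif_pct"].is_monotonic_decreasing
        # strongest predictor leads the table
        assert rep.table.index[0] == "x1"
        assert 0.0 <= rep.msf_selected <= 1.0

    def test_rescaling_leaves_measures_invariant(self, toy_linear):
        rep1 = self.make_report(toy_linear)
        X2 = toy_linear.X.copy()
        X2[:, 1] *= 250.0
        rep2 = self.make_report(toy_linear.with_X(X2))
        for colname in ("vif_pct", "rmsdr", "rcb_x100", "sf"):
            np.testing.assert_allclose(rep1.table[colname],
                                       rep2.table[colname], rtol=1e-8)
        assert rep1.msf_selected == rep2.msf_selected
        pd.testing.assert_frame_equal(rep1.model_frequencies,
                                      rep2.model_frequencies)

    def test_alpha_one_gives_full_model_report(self, toy_linear):
        rep = self.make_report(toy_linear, alpha=1.0)
        assert (rep.table["vif_pct"] == 100.0).all()
        assert rep.msf_selected == 1.0
        assert rep.selected_terms == toy_linear.term_names

    def test_same_seeds_same_report(self, toy_linear):
        r1 = self.make_report(toy_linear)
        r2 = self.make_report(toy_linear)
        assert r1.to_json() == r2.to_json()

    def test_estimate_columns_follow_selection(self, toy_linear):
        rep = self.make_report(toy_linear)
        for col, row in rep.table.iterrows():
            if row["term"] in rep.selected_terms:
                assert np.isfinite(row["estimate_selected"])
            else:
                assert np.isnan(row["estimate_selected"])

    def test_csv_column_order(self, toy_linear, tmp_path):
        rep = self.make_report(toy_linear)
        path = tmp_path / "report.csv"
        rep.to_csv(path)
        header = path.read_text().splitlines()[0].split(",")
        assert header == ["column", "term", "estimate_global", "se_global",
                          "vif_pct", "estimate_selected", "se_selected",
                          "rmsdr", "rcb_x100", "sf", "se_sf", "rcb_caveat"]

    def test_two_scheme_defaults_recorded(self, toy_linear):
        rep = stability_report(toy_linear)
        assert rep.meta["inclusion_plan"]["scheme"] == "subsample"
        assert rep.meta["inclusion_plan"]["proportion"] == 0.5
        assert rep.meta["bias_plan"]["scheme"] == "bootstrap"

    def test_vif_all_matches_scalar(self, toy_linear):
        from selstab import be_selector, resample_and_select
        ens = resample_and_select(toy_linear, bootstrap_plan(B=50, seed=8),
                                  be_selector())
        va = vif_all(ens)
        for t in ens.term_names:
            assert va[t] == vif(ens, t)
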