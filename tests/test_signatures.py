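"""Single-sample scoring against a naive walk oracle; Welch and OLS contracts."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snp2path import synth
from snp2path.signatures import ScoreMatrix, gsva_scores, simple_linreg, signature_panel_report, welch_t
from conftest import random_expr


def gsva_oracle(expr, sets, tau=1.0, kcdf="gaussian", summary="diff"):
    """Step-by-step re-implementation from the stated formulas (pure python)."""
    genes = list(expr.index)
    samples = list(expr.columns)
    p, n = len(genes), len(samples)
    z = {}
    for g in genes:
        vals = [float(expr.loc[g, s]) for s in samples]
        if kcdf == "gaussian":
            h = max(statistics.stdev(vals) / 4.0, 1e-8)
            for s, x in zip(samples, vals):
                z[(g, s)] = sum(0.5 * (1 + math.erf((x - xk) / (h * math.sqrt(2)))) for xk in vals) / n
        else:
            for s, x in zip(samples, vals):
                z[(g, s)] = sum(1 for xk in vals if xk <= x) / n
    out = {}
    for name, members in sets.items():
        mem = set(g for g in members if g in set(genes))
        m = len(mem)
        col = {}
        for s in samples:
            ranked = sorted(genes, key=lambda g: (-z[(g, s)], g))
            r = {g: abs(p / 2.0 - (i + 1)) ** tau for i, g in enumerate(ranked)}
            denom = sum(r[g] for g in mem)
            cum, walk = 0.0, []
            for g in ranked:
                cum += (r[g] / denom) if g in mem else (-1.0 / (p - m))
                walk.append(cum)
            if summary == "diff":
                col[s] = max(max(walk), 0.0) + min(min(walk), 0.0)
            else:
                col[s] = max(walk, key=abs)
        out[name] = col
    return pd.DataFrame(out, index=samples)


class TestGsvaScores:
    @pytest.mark.parametrize("kcdf", ["gaussian", "ecdf"])
    @pytest.mark.parametrize("summary", ["diff", "absmax"])
    def test_matches_walk_oracle(self, rng, kcdf, summary):
        expr = random_expr(rng, p=50, n=12)
        genes = list(expr.index)
        sets = {
            "S8": list(rng.choice(genes, size=8, replace=False)),
            "S15": list(rng.choice(genes, size=15, replace=False)),
        }
        got = gsva_scores(expr, sets, kcdf=kcdf, summary=summary).scores
        want = gsva_oracle(expr, sets, kcdf=kcdf, summary=summary)
        assert np.abs(got - want.loc[got.index, got.columns]).to_numpy().max() < 1e-10

    def test_scores_bounded(self, rng):
        expr = random_expr(rng, p=40, n=10)
        sets = {f"S{k}": list(rng.choice(list(expr.index), size=k, replace=False)) for k in (3, 10, 25)}
        scores = gsva_scores(expr, sets).scores.to_numpy()
        assert (scores >= -1.0 - 1e-12).all() and (scores <= 1.0 + 1e-12).all()

    def test_top_ranked_set_scores_highest(self, rng):
        expr = random_expr(rng, p=30, n=6)
        genes = sorted(expr.index)
        members = genes[:5]
        target = expr.columns[2]
        expr.loc[members, target] = expr.to_numpy().max() + np.arange(5, 0, -1)  # occupy the top ranks
        scores = gsva_scores(expr, {"S": members}).scores["S"]
        assert scores.idxmax() == target and scores[target] > 0

    def test_whole_matrix_set_is_degenerate_zero(self, rng):
        expr = random_expr(rng, p=10, n=4)
        res = gsva_scores(expr, {"ALL": list(expr.index)})
        assert res.degenerate_sets == ["ALL"]
        assert (res.scores["ALL"] == 0.0).all()

    def test_small_set_skipped_with_warning(self, rng):
        expr = random_expr(rng, p=10, n=4)
        with pytest.warns(UserWarning, match="skipped"):
            res = gsva_scores(expr, {"TINY": [expr.index[0]], "OK": list(expr.index[:3])})
        assert res.skipped_sets == ["TINY"] and list(res.scores.columns) == ["OK"]

    def test_constant_matrix_scores_zero(self):
        expr = pd.DataFrame(5.0, index=[f"G{i}" for i in range(8)], columns=[f"S{j}" for j in range(4)])
        res = gsva_scores(expr, {"S": ["G0", "G1", "G2"]})
        assert (res.scores.to_numpy() == 0.0).all()

    def test_monotone_invariance_ecdf_kernel(self, rng):
        """The rank/ECDF kernel is exactly invariant to per-gene monotone maps."""
        expr = random_expr(rng, p=25, n=8)
        sets = {"S": list(rng.choice(list(expr.index), size=7, replace=False))}
        base = gsva_scores(expr, sets, kcdf="ecdf").scores
        warped = expr.copy()
        warped.iloc[0::3] = np.exp(warped.iloc[0::3] / 2.0)
        warped.iloc[1::3] = warped.iloc[1::3] ** 3
        got = gsva_scores(warped, sets, kcdf="ecdf").scores
        assert np.abs(got - base).to_numpy().max() < 1e-12

    def test_affine_invariance_gaussian_kernel(self, rng):
        """The Gaussian kernel statistic is exactly invariant to increasing affine maps."""
        expr = random_expr(rng, p=25, n=8)
        sets = {"S": list(rng.choice(list(expr.index), size=7, replace=False))}
        base = gsva_scores(expr, sets).scores
        warped = expr * 3.5 + 11.0
        got = gsva_scores(warped, sets).scores
        assert np.abs(got - base).to_numpy().max() < 1e-10

    def test_reversed_ranking_approximately_flips_sign(self, rng):
        """Negating the matrix reverses every sample's ranking; scores flip up to O(1/p).

        Uses the Gaussian kernel: negation maps the kernel statistic z to 1 - z
        exactly, reversing the (tie-free) within-sample ranking.
        """
        p = 200
        expr = random_expr(rng, p=p, n=4)
        sets = {"S": list(rng.choice(list(expr.index), size=20, replace=False))}
        base = gsva_scores(expr, sets).scores
        flipped = gsva_scores(-expr, sets).scores
        big = np.abs(base.to_numpy()) > 0.1
        assert (np.sign(flipped.to_numpy()[big]) == -np.sign(base.to_numpy()[big])).all()
        assert np.abs(flipped.to_numpy() + base.to_numpy()).max() < 10.0 / p

    def test_input_contracts(self, rng):
        expr = random_expr(rng, p=10, n=4)
        dup = pd.concat([expr, expr.iloc[[0]]])
        with pytest.raises(ValueError, match="unique"):
            gsva_scores(dup, {"S": list(expr.index[:3])})
        holed = expr.copy()
        holed.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            gsva_scores(holed, {"S": list(expr.index[:3])})


class TestWelch:
    def test_identical_groups(self):
        assert welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])[::2] == (0.0, 1.0)

    def test_worked_example(self):
        t, df, p = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.224745, abs=1e-6)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.2878641, abs=1e-6)

    def test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_degenerate_zero_variance_contract(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 2.0, 1.0)
        t, _, p = welch_t([3.0, 3.0], [2.0, 2.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_agrees_with_scipy_oracle(self, rng):
        for _ in range(300):
            a = rng.normal(size=int(rng.integers(2, 30)))
            b = rng.normal(loc=rng.normal(), scale=float(rng.uniform(0.5, 3)), size=int(rng.integers(2, 30)))
            t, df, p = welch_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestSimpleLinreg:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        slope, intercept, r2, p = simple_linreg(x, 2 * x + 1)
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_orthogonal_x_y(self):
        x = np.array([-1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0])  # zero sample covariance with x
        slope, _, r2, _ = simple_linreg(x, y)
        assert slope == pytest.approx(0.0, abs=1e-12) and r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_x_rejected_and_length_mismatch(self):
        with pytest.raises(ValueError, match="constant"):
            simple_linreg([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="mismatch"):
            simple_linreg([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_agrees_with_scipy_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = rng.normal(scale=2.0, size=n) + float(rng.normal()) * x
            slope, intercept, r2, p = simple_linreg(x, y)
            ref = stats.linregress(x, y)
            assert slope == pytest.approx(ref.slope, abs=1e-10)
            assert intercept == pytest.approx(ref.intercept, abs=1e-10)
            assert r2 == pytest.approx(ref.rvalue**2, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_slope_recovery_from_coupled_metadata(self):
        """Metadata coupled to activity with slope 0.5, noise 0.2, n=40: slope within +/-0.15 in >=90% of 200 runs."""
        ok = 0
        reps = 200
        for i in range(reps):
            cfg = synth.SynthConfig(seed=60_000 + i)
            cfg.n_genes_universe = 200
            cfg.expr_spec = synth.ExprSpec(n_genes=50, n_case=20, n_control=20, set_size=8, n_decoy_sets=0)
            # intercept 10 keeps the SLEDAI-like variable away from its floor at 0
            cfg.meta_spec = synth.MetaSpec(coefficients={"SLEDAI": (10.0, 0.5, 0.2)})
            bundle = synth.gen_expression(cfg)
            slope, *_ = simple_linreg(bundle.activity["SIG_PLANTED"], bundle.metadata["SLEDAI"])
            ok += abs(slope - 0.5) <= 0.15
        assert ok / reps >= 0.90

    def test_zero_coupling_slope_near_zero(self):
        cfg = synth.SynthConfig(seed=77)
        cfg.n_genes_universe = 200
        cfg.expr_spec = synth.ExprSpec(n_genes=50, n_case=20, n_control=20, set_size=8, n_decoy_sets=0)
        cfg.meta_spec = synth.MetaSpec(coefficients={"SLEDAI": (5.0, 0.0, 1.0)})
        bundle = synth.gen_expression(cfg)
        slope, _, _, p = simple_linreg(bundle.activity["SIG_PLANTED"], bundle.metadata["SLEDAI"])
        assert p > 0.05  # slope confidence interval covers 0


class TestPanelReport:
    def _scores_meta(self, rng, n=12):
        idx = [f"S{j:02d}" for j in range(n)]
        scores = ScoreMatrix(
            scores=pd.DataFrame({"SIG_A": rng.normal(size=n), "SIG_B": rng.normal(size=n)}, index=idx),
            params={},
        )
        meta = pd.DataFrame(
            {"group": ["SLE"] * (n // 2) + ["control"] * (n // 2), "SLEDAI": np.linspace(0, 12, n)}, index=idx
        )
        return scores, meta

    def test_subgroup_filter_restricts_n(self, rng):
        scores, meta = self._scores_meta(rng)
        rep = signature_panel_report(
            scores, meta, regressions=[("SIG_A", "SLEDAI")], subset="SLEDAI >= 6"
        )
        assert rep["regressions"].loc[0, "n"] == int((meta["SLEDAI"] >= 6).sum())

    def test_unknown_name_rejected(self, rng):
        scores, meta = self._scores_meta(rng)
        with pytest.raises(ValueError, match="unknown"):
            signature_panel_report(scores, meta, regressions=[("NOPE", "SLEDAI")])

    def test_planted_set_flagged_decoys_mostly_not(self):
        cfg = synth.SynthConfig(seed=99)
        cfg.expr_spec = synth.ExprSpec(n_genes=300, n_case=15, n_control=15, set_size=20, n_decoy_sets=5)
        bundle = synth.gen_expression(cfg)
        scores = gsva_scores(bundle.expr, bundle.sets)
        rep = signature_panel_report(scores, bundle.metadata)
        welch = rep["welch"].set_index("set")
        assert bool(welch.loc["SIG_PLANTED", "flagged"])
        assert welch.drop("SIG_PLANTED")["flagged"].sum() <= 1

    def test_null_panel_type_one_error_nominal(self, rng):
        """Welch flags on null score panels reject at ~5% (1,000 panels)."""
        flags = trials = 0
        for _ in range(1000):
            scores, meta = self._scores_meta(rng, n=16)
            rep = signature_panel_report(scores, meta)
            flags += int(rep["welch"]["flagged"].sum())
            trials += len(rep["welch"])
        rate = flags / trials
        se3 = 3 * np.sqrt(0.05 * 0.95 / trials)
        assert abs(rate - 0.05) <= se3
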