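"""Single-sample gene-set scoring (GSVA-style) and downstream statistics.

The scorer estimates, per gene, a kernel CDF across samples (Gaussian kernel
with bandwidth s_i/4 by default, or a rank/ECDF kernel), ranks genes within
each sample by the resulting expression-level statistic, and runs a
Kolmogorov-Smirnov-like weighted random walk down the ranked list for each
gene set: in-set positions step up by the normalized rank statistic
|p/2 - rank|^tau, out-of-set positions step down by 1/(p - set size). The
per-sample enrichment score is, by default, the magnitude difference
summary — the largest positive walk deviation plus the largest negative
deviation — which is bounded in [-1, 1]; the maximum-absolute-deviation
summary is available as an option.

Downstream, signatures are compared between sample groups with Welch's
unequal-variance t-test (Satterthwaite degrees of freedom) and related to
clinical covariates with simple (ordinary-least-squares) linear regression.

Tie conventions are fixed for determinism: within-sample ranking breaks ties
lexicographically by gene label, and a sample whose statistics are all tied
(e.g. a constant expression matrix) scores 0 for every set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoreMatrix",
    "gsva_scores",
    "welch_t",
    "simple_linreg",
    "signature_panel_report",
]


@dataclass
class ScoreMatrix:
    """Samples x gene-sets enrichment scores plus the parameters that made them."""

    scores: pd.DataFrame
    params: dict
    degenerate_sets: list = field(default_factory=list)
    skipped_sets: list = field(default_factory=list)
    metadata: pd.DataFrame | None = None


def _kernel_stat(X: np.ndarray, kcdf: str) -> np.ndarray:
    """Per-gene CDF estimate evaluated at each observed value (genes x samples)."""
    g, n = X.shape
    Z = np.empty_like(X, dtype=float)
    if kcdf == "gaussian":
        h = X.std(axis=1, ddof=1) / 4.0
        h = np.maximum(h, 1e-8)  # constant genes
        block = max(1, int(2e6 // max(n * n, 1)))
        for lo in range(0, g, block):
            hi = min(lo + block, g)
            diff = (X[lo:hi, :, None] - X[lo:hi, None, :]) / h[lo:hi, None, None]
            Z[lo:hi] = stats.norm.cdf(diff).mean(axis=2)
    elif kcdf == "ecdf":
        for i in range(g):
            Z[i] = (X[i][None, :] <= X[i][:, None]).mean(axis=1)
    else:
        raise ValueError(f"unknown kcdf {kcdf!r} (use 'gaussian' or 'ecdf')")
    return Z


def gsva_scores(
    expr: pd.DataFrame,
    sets: dict[str, list[str]],
    tau: float = 1.0,
    min_set: int = 2,
    kcdf: str = "gaussian",
    summary: str = "diff",
) -> ScoreMatrix:
    """Score every sample against every gene set (see module docstring).

    ``expr`` is genes x samples on the log2 scale with unique gene ids and no
    missing values. Sets with fewer than ``min_set`` genes mapped to the
    matrix are skipped with a warning; a set covering *all* matrix genes has
    no out-of-set steps and scores 0 (flagged degenerate).
    """
    if expr.index.duplicated().any():
        raise ValueError("gene identifiers must be unique")
    if expr.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    p, n = expr.shape
    if p < 3:
        raise ValueError("need at least 3 genes")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if summary not in {"diff", "absmax"}:
        raise ValueError(f"unknown summary {summary!r}")

    genes = expr.index.to_numpy()
    label_order = np.argsort(genes, kind="stable")  # lexicographic tie-break helper
    label_rank = np.empty(p, dtype=int)
    label_rank[label_order] = np.arange(p)

    X = expr.to_numpy(dtype=float)
    Z = _kernel_stat(X, kcdf)

    # rank genes per sample by Z descending, ties by gene label
    order = np.empty((p, n), dtype=int)
    for j in range(n):
        order[:, j] = np.lexsort((label_rank, -Z[:, j]))
    tied_sample = np.ptp(Z, axis=0) == 0.0

    rank_pos = np.arange(1, p + 1, dtype=float)
    rstat = np.abs(p / 2.0 - rank_pos) ** tau  # weight at each rank position

    gene_index = {g: i for i, g in enumerate(genes)}
    degenerate, skipped, cols = [], [], {}
    for name in sets:
        idx = [gene_index[g] for g in sets[name] if g in gene_index]
        m = len(set(idx))
        if m < min_set:
            warnings.warn(f"gene set {name!r}: only {m} genes map to the matrix (min_set={min_set}); skipped")
            skipped.append(name)
            continue
        member = np.zeros(p, dtype=bool)
        member[idx] = True
        if m == p:
            degenerate.append(name)
            cols[name] = np.zeros(n)
            continue
        es = np.empty(n)
        out_step = 1.0 / (p - m)
        for j in range(n):
            if tied_sample[j]:
                es[j] = 0.0
                continue
            in_set = member[order[:, j]]
            denom = rstat[in_set].sum()
            steps = np.where(in_set, (rstat / denom if denom > 0 else rstat * 0.0), -out_step)
            walk = np.cumsum(steps)
            if summary == "diff":
                es[j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
            else:
                es[j] = walk[np.abs(walk).argmax()]
        cols[name] = es
    scores = pd.DataFrame(cols, index=expr.columns)
    params = {"tau": tau, "min_set": min_set, "kcdf": kcdf, "summary": summary}
    return ScoreMatrix(scores=scores, params=params, degenerate_sets=degenerate, skipped_sets=skipped)


def welch_t(scores_a, scores_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-tailed: returns (t, df, p).

    Degenerate contract: two zero-variance samples compare by exact equality
    of means (t = 0, p = 1 when equal; infinite t, p = 0 otherwise).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        return float(np.inf * np.sign(diff)), float(na + nb - 2), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def simple_linreg(x, y) -> tuple[float, float, float, float]:
    """Ordinary least squares of y on x: returns (slope, intercept, R^2, p).

    R^2 is the squared Pearson correlation; p is the two-tailed t-test on the
    slope. Constant x is an error; constant y gives slope 0, R^2 = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("x is constant; regression undefined")
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0.0:
        return 0.0, intercept, 0.0, 1.0
    r2 = sxy * sxy / (sxx * syy)
    rss = syy - slope * sxy
    if rss <= 0.0:  # numerically exact fit
        return float(slope), intercept, 1.0, 0.0
    se = np.sqrt(rss / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return float(slope), intercept, float(r2), float(p)


def signature_panel_report(
    scores: ScoreMatrix,
    metadata: pd.DataFrame,
    group_col: str = "group",
    case: str = "SLE",
    control: str = "control",
    alpha: float = 0.05,
    regressions: list[tuple[str, str]] | None = None,
    subset: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-set Welch table (case vs control) plus a requested regression grid.

    ``regressions`` pairs name either a score column or a metadata column for
    x and y. ``subset`` is a pandas query on the metadata (e.g. "SLEDAI >= 6",
    the active-patient filter) applied to the regression samples only; each
    regression row reports the n actually used.
    """
    if group_col not in metadata.columns:
        raise ValueError(f"metadata lacks group column {group_col!r}")
    meta = metadata.loc[scores.scores.index]
    case_idx = meta.index[meta[group_col] == case]
    ctrl_idx = meta.index[meta[group_col] == control]
    welch_rows = []
    for name in scores.scores.columns:
        t, df, p = welch_t(scores.scores.loc[case_idx, name], scores.scores.loc[ctrl_idx, name])
        welch_rows.append(
            {
                "set": name,
                "mean_case": float(scores.scores.loc[case_idx, name].mean()),
                "mean_control": float(scores.scores.loc[ctrl_idx, name].mean()),
                "t": t, "df": df, "p": p, "flagged": bool(p < alpha),
            }
        )
    report = {"welch": pd.DataFrame(welch_rows)}

    def resolve(name: str, frame_meta: pd.DataFrame, idx) -> np.ndarray:
        if name in scores.scores.columns:
            return scores.scores.loc[idx, name].to_numpy(dtype=float)
        if name in frame_meta.columns:
            return frame_meta.loc[idx, name].to_numpy(dtype=float)
        raise ValueError(f"unknown set or covariate {name!r}")

    reg_rows = []
    sub_meta = meta.query(subset) if subset else meta
    for xname, yname in regressions or []:
        idx = sub_meta.index
        x = resolve(xname, sub_meta, idx)
        y = resolve(yname, sub_meta, idx)
        slope, intercept, r2, p = simple_linreg(x, y)
        reg_rows.append(
            {
                "x": xname, "y": yname, "n": len(idx),
                "slope": slope, "intercept": intercept, "r2": r2, "p": p,
                "significant": bool(p < alpha),
            }
        )
    report["regressions"] = pd.DataFrame(reg_rows)
    return report
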