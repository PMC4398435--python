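"""Phylogenetically controlled regression and supporting statistics.

The centrepiece is PGLS under Pagel's lambda: a generalized least-squares
model y = X beta + eps with eps ~ N(0, sigma^2 V(lambda)), where V is the
Brownian-motion covariance of the phylogeny (V_ij = shared root-to-MRCA
branch length) and lambda in [0, 1] scales the off-diagonal entries.
lambda is estimated by profile maximum likelihood (21-point grid pre-scan,
then bounded Brent refinement) and tested against the lambda = 0 and
lambda = 1 boundaries with likelihood-ratio tests.

Around it sit the pieces the trait analysis needs: an iterative VIF screen
for multicollinear traits, grafting of missing tips onto a clade's stem
branch, externally studentized outlier flagging in the whitened space,
Shapiro-Wilk residual normality, AICc all-subsets ranking with Akaike-
weight model averaging, maximum-likelihood GLS with AR(1) errors for the
temporal-trend contrasts between species groups, and Spearman rank
correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize_scalar

__all__ = [
    "PGLSFit",
    "GLSFit",
    "vif_screen",
    "graft_tips",
    "bm_covariance",
    "lambda_transform",
    "pgls_fit",
    "studentized_outliers",
    "refit_without_outliers",
    "residual_normality",
    "aicc",
    "dredge",
    "model_average",
    "gls_trend",
    "fit_gls_ar1",
    "rank_correlation",
]


# ---------------------------------------------------------------------------
# Trait screening
# ---------------------------------------------------------------------------

def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1 - R^2_j) from regressing column j on the others."""
    n, p = X.shape
    vifs = np.empty(p)
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        y = X[:, j]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            vifs[j] = np.inf
            continue
        r2 = 1 - ss_res / ss_tot
        vifs[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_screen(
    traits: pd.DataFrame, vif_cut: float = 5.0, tolerance_cut: float | None = None
) -> tuple[list[str], pd.Series]:
    """Iteratively drop the highest-VIF trait until all VIF <= cut.

    ``tolerance_cut`` (tolerance = 1/VIF) is accepted as an alternative
    formulation: a trait is also dropped while its tolerance falls below
    the cut. Returns (retained trait names, final VIFs).
    """
    cols = list(traits.columns)
    if len(cols) < 2:
        raise ValueError("need >=2 continuous traits to screen")
    while len(cols) > 1:
        vifs = _vif_values(traits[cols].to_numpy(dtype=float))
        worst = int(np.argmax(vifs))
        offending = vifs[worst] > vif_cut
        if tolerance_cut is not None:
            offending = offending or (1.0 / vifs[worst] < tolerance_cut)
        if not offending:
            break
        cols.pop(worst)
    final = pd.Series(_vif_values(traits[cols].to_numpy(dtype=float)), index=cols)
    return cols, final


# ---------------------------------------------------------------------------
# Tree handling
# ---------------------------------------------------------------------------

def _tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}


def graft_tips(
    tree: dendropy.Tree, placements: Mapping[str, Sequence[str]]
) -> dendropy.Tree:
    """Attach missing species at the midpoint of a clade's stem branch.

    Each placement maps a new tip label to the tip labels of a clade that
    must be monophyletic in the tree. The new tip's pendant branch restores
    ultrametricity, and no pre-existing tip-to-tip distance changes (the
    stem branch is split, not shortened).
    """
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    for new_label, clade_tips in placements.items():
        taxa = [tree.taxon_namespace.get_taxon(t) for t in clade_tips]
        if any(t is None for t in taxa):
            raise ValueError(f"placement clade for {new_label!r} has unknown tips")
        mrca = tree.mrca(taxa=taxa)
        clade_leaf_labels = {lf.taxon.label for lf in mrca.leaf_iter()}
        if clade_leaf_labels != set(clade_tips):
            raise ValueError(
                f"placement clade for {new_label!r} is not monophyletic: "
                f"MRCA spans {sorted(clade_leaf_labels)}"
            )
        if mrca.parent_node is None:
            raise ValueError(f"cannot graft {new_label!r} onto the root clade")
        stem = mrca.edge.length
        if stem is None or stem <= 0:
            raise ValueError(f"clade stem for {new_label!r} has no positive length")
        parent = mrca.parent_node
        # split the stem at its midpoint
        attach = parent.new_child(edge_length=stem / 2.0)
        parent.remove_child(mrca)
        attach.add_child(mrca)
        mrca.edge.length = stem / 2.0
        # pendant length restores ultrametricity
        tree.calc_node_root_distances()
        depth = max(lf.root_distance for lf in tree.leaf_node_iter())
        attach_depth = attach.root_distance if attach.root_distance is not None else 0.0
        pendant = depth - attach_depth
        taxon = tree.taxon_namespace.new_taxon(label=new_label)
        attach.new_child(taxon=taxon, edge_length=pendant)
    return tree


def bm_covariance(tree: dendropy.Tree, tip_order: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance: V_ij = root-to-MRCA shared path length.

    Accumulated by walking the tree once: every edge adds its length to
    the covariance block of the tips below it (V_ij sums the lengths of
    all edges shared by the root-to-tip paths of i and j). Returns
    (V, tip labels in row order).
    """
    depths = _tip_depths(tree)
    labels = list(tip_order) if tip_order is not None else sorted(depths)
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    for node in tree.preorder_node_iter():
        e = node.edge.length
        if e is None or node.parent_node is None:
            continue
        # tips absent from the requested order are skipped, so a tip_order
        # restricted to a subset yields that subset's covariance
        idx = [pos[lf.taxon.label] for lf in node.leaf_iter() if lf.taxon.label in pos]
        V[np.ix_(idx, idx)] += e
    return V, labels


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: off-diagonals scaled by lambda, diagonal untouched."""
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    response: str
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    lam: float
    log_lik: float
    aicc: float
    lrt_p_lambda0: float
    lrt_p_lambda1: float
    n: int
    k: int
    sigma2: float
    V: np.ndarray = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    f_stat: float = np.nan
    f_df: tuple[int, int] = (0, 0)
    f_p: float = np.nan

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "t": self.t, "p": self.p},
            index=self.terms,
        )


def _gls_profile(y: np.ndarray, X: np.ndarray, Vl: np.ndarray):
    """ML profile pieces for fixed covariance: beta, residuals, logLik."""
    n = len(y)
    c, low = cho_factor(Vl, lower=True)
    Vi_X = cho_solve((c, low), X)
    Vi_y = cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = cho_solve((c, low), r)
    rss = float(r @ Vi_r)
    sigma2_ml = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
    return beta, r, rss, sigma2_ml, ll, XtViX


def pgls_fit(
    y: np.ndarray | pd.Series,
    X: np.ndarray | pd.DataFrame,
    V: np.ndarray,
    response: str = "y",
    terms: Sequence[str] | None = None,
    fixed_lambda: float | None = None,
    grid_points: int = 21,
    tol: float = 1e-6,
) -> PGLSFit:
    """PGLS with Pagel's lambda estimated by profile maximum likelihood.

    ``X`` must already include the intercept column. The lambda profile is
    scanned on a uniform grid over [0, 1], then refined by bounded Brent
    search around the best grid point; likelihood-ratio tests against the
    two boundaries use a chi-square with 1 df.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns) if terms is None else list(terms)
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if terms is None:
            terms = [f"x{j}" for j in range(X.shape[1])]
    n, k = X.shape
    if len(y) != n or V.shape != (n, n):
        raise ValueError("y, X and V dimensions disagree")
    if n <= k + 1:
        raise ValueError(f"n = {n} too small for k = {k} terms")
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError(
            f"design matrix is singular; collinear terms among {terms}"
        )

    def nll(lam):
        return -_gls_profile(y, X, lambda_transform(V, lam))[4]

    if fixed_lambda is not None:
        lam_hat = float(fixed_lambda)
    else:
        grid = np.linspace(0.0, 1.0, grid_points)
        vals = [nll(g) for g in grid]
        i = int(np.argmin(vals))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid_points - 1)]
        if hi - lo < 1e-12:
            lam_hat = grid[i]
        else:
            res = minimize_scalar(nll, bounds=(lo, hi), method="bounded", options={"xatol": tol})
            lam_hat = float(res.x)
            if nll(grid[i]) < res.fun:
                lam_hat = float(grid[i])

    Vl = lambda_transform(V, lam_hat)
    beta, r, rss, sigma2_ml, ll, XtViX = _gls_profile(y, X, Vl)
    sigma2 = rss / (n - k)
    cov_beta = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=n - k)

    if fixed_lambda is None:
        ll0 = _gls_profile(y, X, lambda_transform(V, 0.0))[4]
        ll1 = _gls_profile(y, X, lambda_transform(V, 1.0))[4]
        lrt0 = 2 * max(ll - ll0, 0.0)
        lrt1 = 2 * max(ll - ll1, 0.0)
        p0 = float(stats.chi2.sf(lrt0, df=1))
        p1 = float(stats.chi2.sf(lrt1, df=1))
        n_par = k + 2  # beta, sigma^2, lambda
    else:
        p0 = p1 = np.nan
        n_par = k + 1

    # overall regression F (all non-intercept terms)
    f_stat, f_p, f_df = np.nan, np.nan, (0, n - k)
    if k > 1:
        R = np.zeros((k - 1, k))
        R[:, 1:] = np.eye(k - 1)
        Rb = R @ beta
        mid = R @ np.linalg.inv(XtViX) @ R.T
        f_stat = float(Rb @ np.linalg.solve(mid, Rb) / ((k - 1) * sigma2))
        f_df = (k - 1, n - k)
        f_p = float(stats.f.sf(f_stat, *f_df))

    return PGLSFit(
        response=response,
        terms=list(terms),
        beta=beta,
        se=se,
        t=tvals,
        p=pvals,
        lam=lam_hat,
        log_lik=ll,
        aicc=aicc(ll, n_par, n),
        lrt_p_lambda0=p0,
        lrt_p_lambda1=p1,
        n=n,
        k=k,
        sigma2=sigma2,
        V=V,
        X=X,
        y=y,
        f_stat=f_stat,
        f_df=f_df,
        f_p=f_p,
    )


def _whitened(fit: PGLSFit):
    L = cholesky(lambda_transform(fit.V, fit.lam), lower=True)
    yw = solve_triangular(L, fit.y, lower=True)
    Xw = solve_triangular(L, fit.X, lower=True)
    return yw, Xw


def studentized_outliers(fit: PGLSFit, cut: float = 3.0) -> np.ndarray:
    """Indices with |externally studentized residual| > cut (whitened space)."""
    yw, Xw = _whitened(fit)
    n, k = Xw.shape
    Q, _ = np.linalg.qr(Xw)
    h = np.einsum("ij,ij->i", Q, Q)
    e = yw - Xw @ np.linalg.lstsq(Xw, yw, rcond=None)[0]
    sse = float(e @ e)
    denom = np.maximum(1 - h, 1e-12)
    s2_i = (sse - e**2 / denom) / (n - k - 1)
    t_ext = e / np.sqrt(np.maximum(s2_i, 1e-300) * denom)
    return np.nonzero(np.abs(t_ext) > cut)[0]


def refit_without_outliers(fit: PGLSFit, cut: float = 3.0) -> tuple[PGLSFit, np.ndarray]:
    """One removal pass of studentized outliers, then a single refit."""
    flagged = studentized_outliers(fit, cut)
    if flagged.size == 0:
        return fit, flagged
    keep = np.setdiff1d(np.arange(fit.n), flagged)
    if len(keep) <= fit.k + 1:
        raise ValueError("removing outliers would leave too few observations")
    refit = pgls_fit(
        fit.y[keep], fit.X[np.ix_(keep, np.arange(fit.k))],
        fit.V[np.ix_(keep, keep)], response=fit.response, terms=fit.terms,
    )
    return refit, flagged


def residual_normality(fit: PGLSFit) -> float:
    """Shapiro-Wilk p-value on the whitened residuals."""
    yw, Xw = _whitened(fit)
    e = yw - Xw @ np.linalg.lstsq(Xw, yw, rcond=None)[0]
    if not (3 <= len(e) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(e) < 1e-10 * max(1.0, float(np.abs(yw).max())):
        raise ValueError("constant residuals; normality test degenerate")
    return float(stats.shapiro(e).pvalue)


# ---------------------------------------------------------------------------
# AICc, all-subsets, model averaging
# ---------------------------------------------------------------------------

def aicc(log_lik: float, k: int, n: int) -> float:
    """Small-sample AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * log_lik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def dredge(
    y: np.ndarray,
    X: pd.DataFrame,
    V: np.ndarray,
    response: str = "y",
    max_terms: int = 20,
) -> pd.DataFrame:
    """All-subsets PGLS over the non-intercept terms of X, ranked by AICc.

    ``X`` must contain an 'intercept' column, always included. Each subset
    model is refit in full (lambda re-estimated). Returns one row per
    model with term inclusion flags, coefficients, logLik, AICc, delta and
    Akaike weight, sorted by AICc.
    """
    terms = [c for c in X.columns if c != "intercept"]
    if "intercept" not in X.columns:
        raise ValueError("X must contain an 'intercept' column")
    if len(terms) > max_terms:
        raise ValueError(f"{len(terms)} terms would enumerate 2^{len(terms)} models; refusing")
    rows = []
    fits = []
    for r in range(len(terms) + 1):
        for subset in itertools.combinations(terms, r):
            cols = ["intercept", *subset]
            fit = pgls_fit(y, X[cols], V, response=response, terms=cols)
            fits.append(fit)
            row = {"model": "+".join(subset) if subset else "(intercept)"}
            for t in terms:
                row[f"has_{t}"] = t in subset
            for t, b in zip(fit.terms, fit.beta):
                row[f"beta_{t}"] = b
            row.update(log_lik=fit.log_lik, aicc=fit.aicc, lam=fit.lam, k=fit.k)
            rows.append(row)
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table["weight"] = akaike_weights(table["aicc"].to_numpy())
    table = table.sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table.attrs["fits"] = fits
    return table


def model_average(dredge_table: pd.DataFrame, conditional: bool = False) -> pd.DataFrame:
    """Akaike-weight averaged coefficients over the dredge set.

    Full averaging (default) substitutes 0 for a term absent from a model;
    conditional averaging renormalises over the models containing the term.
    """
    terms = [c[len("has_"):] for c in dredge_table.columns if c.startswith("has_")]
    w = dredge_table["weight"].to_numpy()
    out = []
    for t in ["intercept", *terms]:
        col = dredge_table.get(f"beta_{t}")
        betas = np.nan_to_num(col.to_numpy(dtype=float), nan=0.0) if col is not None else np.zeros(len(w))
        present = (
            np.ones(len(w), dtype=bool)
            if t == "intercept"
            else dredge_table[f"has_{t}"].to_numpy(dtype=bool)
        )
        if conditional:
            wt = w * present
            est = float(betas @ wt / wt.sum()) if wt.sum() > 0 else np.nan
        else:
            est = float(betas @ w)
        out.append(
            {"term": t, "estimate": est, "importance": float(w[present].sum())}
        )
    return pd.DataFrame(out).set_index("term")


# ---------------------------------------------------------------------------
# GLS with AR(1) errors (temporal trends between groups)
# ---------------------------------------------------------------------------

@dataclass
class GLSFit:
    phi: float
    beta: np.ndarray
    se: np.ndarray
    terms: list[str]
    sigma2: float
    log_lik: float
    f_tests: pd.DataFrame
    n: int
    k: int


def _ar1_whiten(y: np.ndarray, X: np.ndarray, phi: float):
    """Exact AR(1) whitening of one time-ordered series.

    For a unit-variance AR(1) correlation C (C_ij = phi^|i-j|) the rows
    z_1 = y_1 and z_t = (y_t - phi y_{t-1}) / sqrt(1 - phi^2) satisfy
    W C W' = I, and log|C| = (n - 1) log(1 - phi^2).
    """
    s = np.sqrt(1 - phi**2)
    yw = np.empty_like(y)
    Xw = np.empty_like(X)
    yw[0] = y[0]
    Xw[0] = X[0]
    yw[1:] = (y[1:] - phi * y[:-1]) / s
    Xw[1:] = (X[1:] - phi * X[:-1]) / s
    return yw, Xw


def fit_gls_ar1(
    y: np.ndarray,
    X: np.ndarray,
    series_ids: np.ndarray,
    terms: Sequence[str] | None = None,
    method: str = "REML",
) -> GLSFit:
    """GLS with AR(1) correlation within each series (species).

    Rows must be time-ordered within each series. phi is profiled over
    (-0.98, 0.98) by bounded search on the concentrated log-likelihood;
    REML (default, the convention for mixed/GLS correlation parameters,
    which are noticeably biased under plain ML at short series lengths)
    adds the log|X' Sigma^-1 X| term and divides the profiled variance by
    n - k.
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    series_ids = np.asarray(series_ids)
    n, k = X.shape
    terms = list(terms) if terms is not None else [f"x{j}" for j in range(k)]
    uniq = pd.unique(series_ids)
    n_extra = sum(int((series_ids == s).sum()) - 1 for s in uniq)

    def whiten_all(phi):
        yw_parts, Xw_parts = [], []
        for s in uniq:
            m = series_ids == s
            yw, Xw = _ar1_whiten(y[m], X[m], phi)
            yw_parts.append(yw)
            Xw_parts.append(Xw)
        return np.concatenate(yw_parts), np.vstack(Xw_parts)

    def nll(phi):
        yw, Xw = whiten_all(phi)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        rss = float(r @ r)
        logdet = n_extra * np.log(1 - phi**2)
        if method == "ML":
            sigma2 = rss / n
            return 0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
        sigma2 = rss / (n - k)
        sign, logdet_xtx = np.linalg.slogdet(Xw.T @ Xw)
        return 0.5 * ((n - k) * np.log(2 * np.pi * sigma2) + logdet
                      + logdet_xtx + (n - k))

    res = minimize_scalar(nll, bounds=(-0.98, 0.98), method="bounded", options={"xatol": 1e-6})
    phi = float(res.x)
    yw, Xw = whiten_all(phi)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    sigma2 = float(r @ r) / (n - k)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    return GLSFit(
        phi=phi, beta=beta, se=se, terms=terms, sigma2=sigma2, log_lik=-nll(phi),
        f_tests=pd.DataFrame(), n=n, k=k,
    )


def gls_trend(
    data: pd.DataFrame,
    response: str,
    group_col: str = "group",
    period_col: str = "period_index",
    species_col: str = "species",
) -> GLSFit:
    """Group x period GLS trend model with AR(1) errors within species.

    Fits response ~ group + period + group:period with treatment coding
    (first group alphabetically as reference) and reports Wald F-tests for
    the period, group, and interaction blocks.
    """
    df = data.sort_values([species_col, period_col], kind="mergesort").reset_index(drop=True)
    counts = df.groupby(species_col)[period_col].nunique()
    if (counts < 2).any():
        raise ValueError("every species needs >=2 periods for a temporal trend")
    groups = sorted(df[group_col].unique())
    t = df[period_col].to_numpy(dtype=float)
    cols = {"intercept": np.ones(len(df)), "period": t}
    for g in groups[1:]:
        ind = (df[group_col] == g).to_numpy(dtype=float)
        cols[f"group[{g}]"] = ind
        cols[f"group[{g}]:period"] = ind * t
    X = np.column_stack(list(cols.values()))
    terms = list(cols)
    fit = fit_gls_ar1(df[response].to_numpy(), X, df[species_col].to_numpy(), terms)

    # Wald F blocks
    def block_f(names):
        idx = [terms.index(nm) for nm in names]
        R = np.zeros((len(idx), len(terms)))
        for r_i, j in enumerate(idx):
            R[r_i, j] = 1.0
        # rebuild whitened design for the coefficient covariance
        Xw_parts = []
        for s in pd.unique(df[species_col]):
            m = (df[species_col] == s).to_numpy()
            _, Xw = _ar1_whiten(df[response].to_numpy()[m], X[m], fit.phi)
            Xw_parts.append(Xw)
        Xw = np.vstack(Xw_parts)
        cov = fit.sigma2 * np.linalg.inv(Xw.T @ Xw)
        Rb = R @ fit.beta
        fstat = float(Rb @ np.linalg.solve(R @ cov @ R.T, Rb) / len(idx))
        df1, df2 = len(idx), fit.n - fit.k
        return fstat, df1, df2, float(stats.f.sf(fstat, df1, df2))

    rows = []
    blocks = {
        "period": ["period"],
        "group": [f"group[{g}]" for g in groups[1:]],
        "group:period": [f"group[{g}]:period" for g in groups[1:]],
    }
    for name, cols_b in blocks.items():
        if not cols_b:
            continue
        fstat, df1, df2, p = block_f(cols_b)
        rows.append({"effect": name, "F": fstat, "df1": df1, "df2": df2, "p": p})
    fit.f_tests = pd.DataFrame(rows).set_index("effect")
    return fit


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman's rho with mid-rank ties and t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
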