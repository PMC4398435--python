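"""Presence-background suitability modelling.

The estimator is the background-normalised exponential (Gibbs) model with
an L1 penalty — the operative core of maximum-entropy niche modelling.
With feature vector f(x) (linear, quadratic and pairwise-product terms,
min-max scaled to [0,1] on the training data) the model places a density
over the background cells,

    q(x) = exp(beta . f(x)) / Z,   Z = sum_bg exp(beta . f(x_b)),

and beta minimises the penalised negative log-likelihood

    -mean_presence[beta . f(x)] + log Z + sum_j lambda_j |beta_j|.

At the optimum each feature's expectation under q matches its presence
mean to within lambda_j — the regularised moment-matching property. The
per-feature lambda_j follow the published feature-class default schedule
scaled by the presence-sample feature spread, times a global multiplier.

Replication follows the record-count rule: fewer than 30 presences -> 10
bootstrap replicates (out-of-bag presences held out), 30 or more -> 4-fold
cross-validation stratified by period. Predictions use the complementary
log-log transform of the raw density by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .env_stack import EnvStack

__all__ = [
    "FeatureExpansion",
    "PBModel",
    "ReplicateSet",
    "TooFewRecordsError",
    "expand_features",
    "choose_replication",
    "fit_pb_model",
    "fit_replicates",
    "predict_map",
    "predict_suitability",
]


class TooFewRecordsError(ValueError):
    """Species has too few presences to fit any replicate scheme."""


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

@dataclass
class FeatureExpansion:
    """Linear + quadratic + pairwise-product features with [0,1] scaling."""

    base_variables: list[str]
    features: list[tuple[str, tuple[str, ...]]]  # (kind, operand names)
    scaling: list[tuple[float, float]]           # per feature (min, max)

    @property
    def names(self) -> list[str]:
        out = []
        for kind, ops in self.features:
            if kind == "linear":
                out.append(ops[0])
            elif kind == "quadratic":
                out.append(f"{ops[0]}^2")
            else:
                out.append(f"{ops[0]}*{ops[1]}")
        return out

    def raw_features(self, table: pd.DataFrame | Mapping[str, np.ndarray]) -> np.ndarray:
        cols = {v: np.asarray(table[v], dtype=float) for v in self.base_variables}
        mats = []
        for kind, ops in self.features:
            if kind == "linear":
                mats.append(cols[ops[0]])
            elif kind == "quadratic":
                mats.append(cols[ops[0]] ** 2)
            else:
                mats.append(cols[ops[0]] * cols[ops[1]])
        return np.column_stack(mats)

    def design_matrix(self, table, clamp: bool = False) -> np.ndarray:
        """Scaled feature matrix; clamp=True pins values outside the
        training range to [0,1] (the extrapolation guard used when
        projecting onto new climates)."""
        raw = self.raw_features(table)
        lo = np.array([s[0] for s in self.scaling])
        hi = np.array([s[1] for s in self.scaling])
        scaled = (raw - lo) / (hi - lo)
        if clamp:
            scaled = np.clip(scaled, 0.0, 1.0)
        return scaled


def expand_features(
    table: pd.DataFrame, base_variables: Sequence[str]
) -> tuple[FeatureExpansion, np.ndarray]:
    """Build the linear/quadratic/product expansion from training rows.

    Columns are ordered all linear terms, then all quadratic terms, then
    products in lexicographic pair order of the base-variable ordering.
    Variables constant on the training data are excluded entirely (their
    min-max scaling is undefined), with a warning.
    """
    base_variables = list(base_variables)
    if not base_variables:
        raise ValueError("need at least one base variable")
    kept = []
    for v in base_variables:
        col = np.asarray(table[v], dtype=float)
        if np.nanmax(col) == np.nanmin(col):
            warnings.warn(f"variable {v!r} is constant on training data; excluded")
        else:
            kept.append(v)
    if not kept:
        raise ValueError("all variables constant on training data")
    features: list[tuple[str, tuple[str, ...]]] = []
    features += [("linear", (v,)) for v in kept]
    features += [("quadratic", (v,)) for v in kept]
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            features.append(("product", (kept[i], kept[j])))
    exp = FeatureExpansion(base_variables=kept, features=features, scaling=[])
    raw = exp.raw_features(table)
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    hi = np.where(hi > lo, hi, lo + 1.0)  # degenerate guard; cannot occur for kept vars' linear terms
    exp.scaling = list(zip(lo.tolist(), hi.tolist()))
    return exp, exp.design_matrix(table)


# ---------------------------------------------------------------------------
# Regularisation schedule
# ---------------------------------------------------------------------------

# Published feature-class default multipliers, interpolated on presence count.
_REG_TABLE = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "product": ([0, 10, 17, 30, 100], [2.6, 1.6, 0.9, 0.55, 0.05]),
}


def default_regularization(
    expansion: FeatureExpansion, presence_design: np.ndarray, multiplier: float = 1.0
) -> np.ndarray:
    """Per-feature L1 weights: class schedule x presence spread / sqrt(m)."""
    m = presence_design.shape[0]
    lam = np.empty(presence_design.shape[1])
    sd = presence_design.std(axis=0, ddof=0)
    for j, (kind, _) in enumerate(expansion.features):
        xs, ys = _REG_TABLE[kind]
        base = float(np.interp(min(m, xs[-1]), xs, ys))
        lam[j] = multiplier * base * max(sd[j], 1e-3) / np.sqrt(max(m, 1))
    return lam


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class PBModel:
    expansion: FeatureExpansion
    coefficients: np.ndarray
    log_z: float                 # log normaliser over training background
    regularization: np.ndarray
    entropy: float               # entropy of the fitted density over training background
    converged: bool
    grad_norm: float
    output_transform: Literal["raw", "cloglog"] = "cloglog"

    def linear_predictor(self, table, clamp: bool = True) -> np.ndarray:
        X = self.expansion.design_matrix(table, clamp=clamp)
        return X @ self.coefficients


def pb_objective(beta: np.ndarray, Xp: np.ndarray, Xb: np.ndarray, lam: np.ndarray) -> float:
    """Penalised negative log-likelihood (the quantity fit_pb_model minimises)."""
    return float(-(Xp @ beta).mean() + logsumexp(Xb @ beta) + np.abs(beta) @ lam)


def _l1_quadratic_cd(g, H, beta, lam, n_sweeps: int = 300, tol: float = 1e-11):
    """Solve min_d g.d + 0.5 d'Hd + lam.|beta + d| by coordinate descent.

    The inner subproblem of the proximal-Newton outer loop. Soft-threshold
    coordinate updates handle sign changes exactly, so there is no
    active-set chatter; dimensions are the feature count, so sweeps are
    cheap.
    """
    k = len(g)
    d = np.zeros(k)
    Hd = np.zeros(k)
    for _ in range(n_sweeps):
        max_change = 0.0
        for j in range(k):
            hjj = max(H[j, j], 1e-12)
            gj = g[j] + Hd[j] - H[j, j] * d[j]
            u = hjj * beta[j] - gj
            z = np.sign(u) * max(abs(u) - lam[j], 0.0) / hjj
            delta = z - (beta[j] + d[j])
            if delta != 0.0:
                Hd += H[:, j] * delta
                d[j] += delta
                max_change = max(max_change, abs(delta))
        if max_change < tol:
            break
    return d


def fit_pb_model(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    base_variables: Sequence[str],
    reg_multiplier: float = 1.0,
    output_transform: Literal["raw", "cloglog"] = "cloglog",
    max_iter: int = 500,
    tol: float = 1e-6,
    init_beta: np.ndarray | None = None,
) -> PBModel:
    """Fit the L1-penalised Gibbs model to presence vs background rows.

    Optimisation is proximal Newton: at each outer step the smooth part is
    replaced by its local quadratic model (gradient = background-model
    expectation minus presence mean, Hessian = feature covariance under
    the fitted density), the L1-penalised quadratic subproblem is solved
    by soft-threshold coordinate descent, and an Armijo backtracking line
    search on the true penalised objective accepts the step. A tiny
    quadratic stabiliser (1e-8 ||beta||^2) keeps the optimum finite under
    complete separation and the Hessian positive definite; it is orders of
    magnitude below the L1 weights for any plausible coefficient size.
    Convergence is declared on the KKT conditions: each feature's
    background-model expectation within lambda_j of its presence mean
    (slack ``tol``) for inactive features, gradient + lambda*sign = 0 for
    active ones.
    """
    if len(presence) < 1 or len(background) < 2:
        raise ValueError("need >=1 presence and >=2 background rows")
    train = pd.concat([presence, background], ignore_index=True)
    expansion, _ = expand_features(train, base_variables)
    Xp = expansion.design_matrix(presence)
    Xb = expansion.design_matrix(background)
    lam = default_regularization(expansion, Xp, reg_multiplier)
    k = Xp.shape[1]
    fbar = Xp.mean(axis=0)
    kkt_tol = max(tol, 1e-8)
    eps = 1e-8  # elastic stabiliser

    def penalised(beta):
        return float(-(fbar @ beta) + logsumexp(Xb @ beta) + eps * (beta @ beta)
                     + lam @ np.abs(beta))

    beta = np.zeros(k) if init_beta is None else np.asarray(init_beta, dtype=float).copy()
    grad_norm = np.inf
    for _ in range(max_iter):
        eta = Xb @ beta
        lse = logsumexp(eta)
        w = np.exp(eta - lse)
        mean_q = Xb.T @ w
        g = mean_q - fbar + 2 * eps * beta
        # KKT residual of the penalised problem
        kkt = np.maximum(np.abs(g) - lam, 0.0)
        active = beta != 0
        kkt[active] = np.abs(g[active] + np.sign(beta[active]) * lam[active])
        grad_norm = float(np.max(kkt)) if k else 0.0
        if grad_norm < kkt_tol:
            break
        H = (Xb * w[:, None]).T @ Xb - np.outer(mean_q, mean_q)
        H[np.diag_indices_from(H)] += 2 * eps
        d = _l1_quadratic_cd(g, H, beta, lam)
        if not np.any(d):
            break
        f0 = penalised(beta)
        step = 1.0
        accepted = False
        for _ls in range(60):
            cand = beta + step * d
            if penalised(cand) < f0 - 1e-14 * max(abs(f0), 1.0):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        beta = cand
    converged = grad_norm < max(kkt_tol * 100, 1e-5)
    if not converged:
        raise RuntimeError(
            f"presence-background fit did not converge: KKT residual {grad_norm:.3g}"
        )
    eta_b = Xb @ beta
    log_z = float(logsumexp(eta_b))
    logq = eta_b - log_z
    entropy = float(-(np.exp(logq) * logq).sum())
    return PBModel(
        expansion=expansion,
        coefficients=beta,
        log_z=log_z,
        regularization=lam,
        entropy=entropy,
        converged=converged,
        grad_norm=grad_norm,
        output_transform=output_transform,
    )


def predict_suitability(model: PBModel, table, clamp: bool = True) -> np.ndarray:
    """Per-row suitability: raw density (relative to training background
    normaliser) or its cloglog transform 1 - exp(-e^H q)."""
    eta = model.linear_predictor(table, clamp=clamp)
    raw = np.exp(eta - model.log_z)
    if model.output_transform == "raw":
        return raw
    return 1.0 - np.exp(-np.exp(model.entropy) * raw)


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------

@dataclass
class ReplicateSet:
    scheme: Literal["bootstrap10", "cv4fold"]
    models: list[PBModel]
    test_indices: list[np.ndarray]  # presence-row indices held out per replicate

    def mean_prediction(self, table, clamp: bool = True) -> np.ndarray:
        preds = [predict_suitability(m, table, clamp=clamp) for m in self.models]
        return np.mean(preds, axis=0)


def choose_replication(n_presences: int, minimum_records: int = 8) -> str:
    """Record-count rule: <30 -> bootstrap10, >=30 -> cv4fold.

    Below ``minimum_records`` the species cannot support any scheme and is
    flagged unmodellable-by-data.
    """
    if n_presences < minimum_records:
        raise TooFewRecordsError(
            f"{n_presences} presences < minimum {minimum_records}: unmodellable by data"
        )
    return "bootstrap10" if n_presences < 30 else "cv4fold"


def _stratified_folds(periods: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Assign presences to folds, stratified by period, seeded."""
    fold = np.empty(len(periods), dtype=int)
    for per in np.unique(periods):
        idx = np.nonzero(periods == per)[0]
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(perm)) % n_folds
    return fold


def fit_replicates(
    scheme: str,
    presence: pd.DataFrame,
    background: pd.DataFrame,
    base_variables: Sequence[str],
    seed: int = 0,
    reg_multiplier: float = 1.0,
    output_transform: Literal["raw", "cloglog"] = "cloglog",
) -> ReplicateSet:
    """Fit the replicate models for the chosen scheme.

    bootstrap10 resamples presences with replacement (background fixed) and
    holds out the out-of-bag presences; cv4fold splits presences into four
    period-stratified folds. Identical seeds give identical replicate sets.
    Replicate fits warm-start from a fit to the full presence set (their
    optima are close, so this cuts solver iterations without changing the
    solution each replicate converges to).
    """
    rng = np.random.default_rng(seed)
    n = len(presence)
    models, test_idx = [], []
    periods = presence["period"].to_numpy() if "period" in presence else np.zeros(n)
    full = fit_pb_model(
        presence, background, base_variables,
        reg_multiplier=reg_multiplier, output_transform=output_transform,
    )
    warm = full.coefficients
    if scheme == "bootstrap10":
        splits = []
        for _ in range(10):
            take = rng.integers(0, n, size=n)
            splits.append((take, np.setdiff1d(np.arange(n), take)))
    elif scheme == "cv4fold":
        fold = _stratified_folds(periods, 4, rng)
        splits = []
        for f in range(4):
            test = np.nonzero(fold == f)[0]
            if len(test) == 0:
                raise ValueError(
                    "cross-validation fold with zero test presences; use bootstrap"
                )
            splits.append((np.nonzero(fold != f)[0], test))
    else:
        raise ValueError(f"unknown replication scheme {scheme!r}")
    for train, test in splits:
        m = fit_pb_model(
            presence.iloc[train], background, base_variables,
            reg_multiplier=reg_multiplier, output_transform=output_transform,
            init_beta=warm,
        )
        models.append(m)
        test_idx.append(test)
    return ReplicateSet(scheme=scheme, models=models, test_indices=test_idx)


# ---------------------------------------------------------------------------
# Raster prediction
# ---------------------------------------------------------------------------

def predict_map(model_or_set: PBModel | ReplicateSet, stack: EnvStack) -> np.ndarray:
    """Project suitability onto a stack's grid (nodata propagated).

    For a ReplicateSet the map is the arithmetic mean of the replicate
    maps. Feature scaling is clamped to the training [0,1] range so
    projections never extrapolate the exponential response.
    """
    if isinstance(model_or_set, ReplicateSet):
        exp = model_or_set.models[0].expansion
    else:
        exp = model_or_set.expansion
    missing = set(exp.base_variables) - set(stack.variable_names)
    if missing:
        raise KeyError(f"stack missing variables: {sorted(missing)}")
    grid = stack.grid
    mask = stack.nodata_mask()
    table = {v: stack.layers[v].ravel() for v in exp.base_variables}
    flat_valid = ~mask.ravel()
    sub = {v: np.where(np.isnan(table[v]), 0.0, table[v]) for v in table}
    if isinstance(model_or_set, ReplicateSet):
        vals = model_or_set.mean_prediction(sub)
    else:
        vals = predict_suitability(model_or_set, sub)
    out = np.where(flat_valid, vals, np.nan).reshape(grid.n_rows, grid.n_cols)
    return out
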