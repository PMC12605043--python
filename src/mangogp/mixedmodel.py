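"""REML estimation and BLUP prediction for the single-kernel GBLUP model.

Model: y = Xb + Za + e with a ~ N(0, sigma_a^2 G) and e ~ N(0, sigma_e^2 I).
The restricted likelihood is profiled down to the single variance ratio
delta = sigma_e^2 / sigma_a^2 using one spectral decomposition of
K = Z G Z' (EMMA-style), then maximised over log delta by a dense coarse
scan followed by bounded refinement. Fixed effects are estimated by GLS at
the optimum; breeding values for every individual in the GRM (phenotyped
or not) come from the BLUP expression a_hat = G Z' H^{-1} (y - X b_hat)
with H = K + delta I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .relmat import GRM

__all__ = [
    "REMLFit",
    "reml_fit",
    "predict_gebv",
    "heritability",
    "fixed_snp_blues",
    "build_design",
]

LOG_DELTA_BOUNDS = (np.log(1e-6), np.log(1e6))
_COARSE_GRID = 256
_VAR_FLOOR = 1e-12


@dataclass
class REMLFit:
    """Variance components, fixed-effect BLUEs and GEBVs from one REML fit."""

    sigma2_a: float
    sigma2_e: float
    delta: float
    loglik: float
    aic: float
    blues: pd.Series
    blue_se: pd.Series
    gebv: pd.Series
    boundary: bool
    converged: bool
    n_records: int
    n_fixed: int
    n_var_params: int = 2
    extra: dict = field(default_factory=dict)

    @property
    def h2(self) -> float:
        return heritability(self)


def build_design(
    index,
    covariates: pd.DataFrame | None = None,
    pc_scores: pd.DataFrame | None = None,
    snp_dosages: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the fixed-effect design: intercept, covariates, PCs, SNPs.

    All pieces are aligned (reindexed) to ``index``; SNP columns are
    prefixed ``snp:`` so their BLUEs can be retrieved by marker id.
    """
    index = pd.Index(index)
    parts = [pd.DataFrame({"intercept": np.ones(len(index))}, index=index)]
    if covariates is not None:
        parts.append(covariates.reindex(index))
    if pc_scores is not None:
        parts.append(pc_scores.reindex(index))
    if snp_dosages is not None:
        snp = snp_dosages.reindex(index)
        snp.columns = [f"snp:{c}" for c in snp.columns]
        parts.append(snp)
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"design columns with missing values: {bad}")
    return X


def _check_full_rank(X: np.ndarray, names) -> None:
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        collinear = [names[i] for i in piv[rank:]]
        raise ValueError(f"design matrix rank-deficient; collinear columns: {collinear}")


def reml_fit(
    y,
    X: pd.DataFrame,
    grm: GRM,
    record_ids=None,
    tol: float = 1e-8,
) -> REMLFit:
    """Fit the GBLUP mixed model by REML.

    Parameters
    ----------
    y : array-like or Series
        Phenotypic records (training individuals only).
    X : DataFrame
        Fixed-effect design, one row per record (see :func:`build_design`).
    grm : GRM
        Relationship matrix over all individuals, training and validation
        alike; must be positive (semi-)definite -- apply
        :func:`mangogp.relmat.bend` first if it is not.
    record_ids : sequence, optional
        Individual id per record (repeated ids = repeated records).
        Defaults to ``y.index`` when ``y`` is a Series.
    """
    if record_ids is None:
        if not isinstance(y, pd.Series):
            raise ValueError("record_ids required when y is not a Series")
        record_ids = y.index
    y = np.asarray(y, dtype=float)
    n = y.size
    Xv = np.asarray(X, dtype=float)
    p = Xv.shape[1]
    if Xv.shape[0] != n or len(record_ids) != n:
        raise ValueError("y, X and record_ids must have matching lengths")
    if n <= p + 1:
        raise ValueError("need n_records > n_fixed_effects + 1")
    _check_full_rank(Xv, list(X.columns))

    ridx = grm.index_of(record_ids)
    K = grm.matrix[np.ix_(ridx, ridx)]
    s, U = np.linalg.eigh(K)
    if s[0] < -1e-8 * max(1.0, abs(s[-1])):
        raise ValueError(
            "relationship matrix is not positive semi-definite; apply relmat.bend"
        )
    s = np.maximum(s, 0.0)
    yt = U.T @ y
    Xt = U.T @ Xv

    def neg_restricted(log_delta: float) -> float:
        return -_profiled_reml(np.exp(log_delta), s, yt, Xt, n, p)[0]

    lo, hi = LOG_DELTA_BOUNDS
    grid = np.linspace(lo, hi, _COARSE_GRID)
    vals = np.array([neg_restricted(g) for g in grid])
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, _COARSE_GRID - 1)]
    res = scipy.optimize.minimize_scalar(
        neg_restricted, bounds=(a, b), method="bounded", options={"xatol": tol}
    )
    log_delta = float(res.x) if res.fun <= vals[k] else float(grid[k])
    delta = float(np.exp(log_delta))

    loglik, sigma2_a, beta, cov_beta = _profiled_reml(
        delta, s, yt, Xt, n, p, want_effects=True
    )
    sigma2_a = max(sigma2_a, _VAR_FLOOR)
    sigma2_e = delta * sigma2_a
    boundary = bool((log_delta - lo < 1e-3) or (hi - log_delta < 1e-3))

    # BLUP of additive effects for every individual in the GRM
    resid = yt - Xt @ beta
    alpha = U @ (resid / (s + delta))
    gebv_all = grm.matrix[:, ridx] @ alpha
    blue_se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0) * sigma2_a)

    aic = -2.0 * loglik + 2.0 * 2
    return REMLFit(
        sigma2_a=float(sigma2_a),
        sigma2_e=float(sigma2_e),
        delta=delta,
        loglik=float(loglik),
        aic=float(aic),
        blues=pd.Series(beta, index=X.columns, name="blue"),
        blue_se=pd.Series(blue_se, index=X.columns, name="se"),
        gebv=pd.Series(gebv_all, index=pd.Index(grm.ids, name="id"), name="gebv"),
        boundary=boundary,
        converged=bool(getattr(res, "success", True)),
        n_records=n,
        n_fixed=p,
    )


def _profiled_reml(delta, s, yt, Xt, n, p, want_effects=False):
    """Profiled restricted log-likelihood at a given variance ratio."""
    d = s + delta
    Xd = Xt / d[:, None]
    A = Xt.T @ Xd
    b = Xd.T @ yt
    cho = scipy.linalg.cho_factor(A)
    beta = scipy.linalg.cho_solve(cho, b)
    resid = yt - Xt @ beta
    q = float(resid @ (resid / d))
    sigma2_a = max(q / (n - p), _VAR_FLOOR)
    logdet_A = 2.0 * np.sum(np.log(np.diag(cho[0])))
    loglik = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2_a) + 1.0)
        + np.sum(np.log(d))
        + logdet_A
    )
    if not want_effects:
        return loglik, sigma2_a
    cov_beta = scipy.linalg.cho_solve(cho, np.eye(p))
    return loglik, sigma2_a, beta, cov_beta


def restricted_loglik_grid(y, X, grm, record_ids=None, n_points: int = 1000):
    """Dense grid of the profiled restricted log-likelihood over log delta.

    Returns (log_delta_grid, loglik_values); used as an independent check
    that the optimiser attains the grid maximum.
    """
    if record_ids is None:
        record_ids = y.index
    y = np.asarray(y, dtype=float)
    Xv = np.asarray(X, dtype=float)
    n, p = Xv.shape
    ridx = grm.index_of(record_ids)
    K = grm.matrix[np.ix_(ridx, ridx)]
    s, U = np.linalg.eigh(K)
    s = np.maximum(s, 0.0)
    yt, Xt = U.T @ y, U.T @ Xv
    grid = np.linspace(*LOG_DELTA_BOUNDS, n_points)
    vals = np.array([_profiled_reml(np.exp(g), s, yt, Xt, n, p)[0] for g in grid])
    return grid, vals


def predict_gebv(fit: REMLFit, individuals) -> pd.Series:
    """GEBVs of the requested individuals (phenotyped or not)."""
    missing = [i for i in individuals if i not in fit.gebv.index]
    if missing:
        raise KeyError(f"individuals absent from the GRM used at fit time: {missing[:5]}")
    return fit.gebv.loc[list(individuals)]


def heritability(fit: REMLFit) -> float:
    """Narrow-sense heritability h2 = sigma_a^2 / (sigma_a^2 + sigma_e^2)."""
    total = fit.sigma2_a + fit.sigma2_e
    if total <= 0:
        raise ValueError("both variance components are zero; h2 undefined")
    return float(fit.sigma2_a / total)


def fixed_snp_blues(fit: REMLFit, snp_ids) -> pd.Series:
    """Per-copy fixed-effect estimates (BLUEs) for named SNP columns."""
    keys = [f"snp:{s}" for s in snp_ids]
    missing = [k for k in keys if k not in fit.blues.index]
    if missing:
        raise KeyError(f"SNPs not fitted as fixed effects: {missing}")
    out = fit.blues.loc[keys]
    out.index = list(snp_ids)
    return out
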