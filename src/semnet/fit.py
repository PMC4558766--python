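"""Maximum-likelihood fitting of recursive SEMs to covariance structure.

Only covariances are modeled; means are saturated and carried through
untouched. For a recursive model with diagonal residual covariance the ML
discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

factorizes into independent pieces: one linear regression per endogenous
gene (solved in closed form from S) and one term for the exogenous
covariance block (closed form when the free-covariance pattern is empty or
complete, quasi-Newton with log-transformed variances otherwise). The
factorized solution is the exact global ML minimizer, so fits are
deterministic and fast enough for exhaustive candidate scans.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .model import ParameterSet, PathModel, check_identifiability

__all__ = [
    "SampleMoments",
    "FitStats",
    "FitResult",
    "NotPositiveDefiniteError",
    "implied_covariance",
    "ml_discrepancy",
    "fit_model",
    "compute_fit_statistics",
]

GRADIENT_TOL = 1e-6
MAX_ITER = 500


class NotPositiveDefiniteError(ValueError):
    """A covariance matrix that must be positive definite is not."""


def _chol_or_raise(m: np.ndarray, name: str) -> np.ndarray:
    try:
        return linalg.cholesky(m, lower=True)
    except linalg.LinAlgError:
        raise NotPositiveDefiniteError(
            f"{name} is not positive definite; possible causes: too few samples "
            "relative to variables, collinear columns, or a constant column"
        ) from None


@dataclass(frozen=True)
class SampleMoments:
    """Sample covariance matrix, means and size for an ordered variable set."""

    S: np.ndarray
    means: np.ndarray
    n: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        means = np.asarray(self.means, dtype=float)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "labels", tuple(self.labels))
        p = len(self.labels)
        if S.shape != (p, p):
            raise ValueError(f"S has shape {S.shape}, expected ({p}, {p})")
        if means.shape != (p,):
            raise ValueError(f"means has shape {means.shape}, expected ({p},)")
        if len(set(self.labels)) != p:
            raise ValueError("variable labels must be distinct")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        _chol_or_raise(S, "sample covariance matrix")

    @classmethod
    def from_data(cls, data: pd.DataFrame) -> "SampleMoments":
        """Moments of a samples x genes data frame (denominator n - 1)."""
        x = data.to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError("expression data contain missing values")
        return cls(
            S=np.cov(x, rowvar=False, ddof=1),
            means=x.mean(axis=0),
            n=x.shape[0],
            labels=tuple(map(str, data.columns)),
        )

    def subset(self, labels: tuple[str, ...] | list[str]) -> "SampleMoments":
        idx = [self.labels.index(g) for g in labels]
        return SampleMoments(
            S=self.S[np.ix_(idx, idx)],
            means=self.means[idx],
            n=self.n,
            labels=tuple(labels),
        )


@dataclass(frozen=True)
class FitStats:
    """Discrepancy-based fit statistics and penalized criteria.

    Conventions: chi_square = (n - 1) * F_ML; information criteria use the
    chi^2 + penalty * t form (AIC = chi^2 + 2t, BIC = chi^2 + t ln n,
    CAIC = chi^2 + t (ln n + 1)). Differences between models on the same
    data are invariant to the additive-constant convention.
    """

    f_ml: float
    chi_square: float
    t: int
    df: int
    gfi: float
    agfi: float  # NaN when df == 0
    pgfi: float
    aic: float
    caic: float
    bic: float


@dataclass(frozen=True)
class FitResult:
    model: PathModel
    theta: ParameterSet
    implied_sigma: np.ndarray
    stats: FitStats
    converged: bool
    iterations: int
    gradient_norm: float
    moments: SampleMoments = field(repr=False, compare=False, default=None)

    def to_json(self) -> str:
        rows = []
        for (s, t), v in sorted(self.theta.path_coefficients.items()):
            rows.append({"name": f"{s}->{t}", "source": s, "target": t, "estimate": v})
        for g, v in sorted(self.theta.exo_variances.items()):
            rows.append({"name": f"var({g})", "source": g, "target": g, "estimate": v})
        for (a, b), v in sorted(self.theta.exo_covariances.items()):
            rows.append({"name": f"cov({a},{b})", "source": a, "target": b, "estimate": v})
        for g, v in sorted(self.theta.residual_variances.items()):
            rows.append({"name": f"resid({g})", "source": g, "target": g, "estimate": v})
        s = self.stats
        return json.dumps(
            {
                "parameters": rows,
                "stats": {
                    "f_ml": s.f_ml, "chi_square": s.chi_square, "t": s.t, "df": s.df,
                    "gfi": s.gfi, "agfi": None if math.isnan(s.agfi) else s.agfi,
                    "pgfi": s.pgfi, "aic": s.aic, "caic": s.caic, "bic": s.bic,
                },
                "convergence": {
                    "converged": self.converged,
                    "iterations": self.iterations,
                    "gradient_norm": self.gradient_norm,
                },
            },
            indent=2,
        )


def implied_covariance(model: PathModel, theta: ParameterSet) -> np.ndarray:
    """Model-implied covariance Sigma(theta) in the model's variable order.

    Writing the full system x = A x + e with cov(e) = blockdiag(Phi, Psi),
    Sigma = (I - A)^-1 D (I - A)^-T; equivalently the familiar blocks
    (I-B)^-1 (Gamma Phi Gamma' + Psi) (I-B)^-T, (I-B)^-1 Gamma Phi, and Phi.
    """
    theta.validate_against(model)
    genes = model.genes
    p = len(genes)
    idx = {g: i for i, g in enumerate(genes)}

    a = np.zeros((p, p))
    for (s, t), v in theta.path_coefficients.items():
        a[idx[t], idx[s]] = v

    d = np.zeros((p, p))
    for g, v in theta.exo_variances.items():
        d[idx[g], idx[g]] = v
    for (g1, g2), v in theta.exo_covariances.items():
        d[idx[g1], idx[g2]] = d[idx[g2], idx[g1]] = v
    for g, v in theta.residual_variances.items():
        d[idx[g], idx[g]] = v

    if model.exogenous:
        exo_idx = [idx[g] for g in model.exogenous]
        _chol_or_raise(d[np.ix_(exo_idx, exo_idx)], "Phi")

    ima_inv = np.linalg.solve(np.eye(p) - a, np.eye(p))
    sigma = ima_inv @ d @ ima_inv.T
    return (sigma + sigma.T) / 2.0


def ml_discrepancy(S: np.ndarray, sigma: np.ndarray, p: int | None = None) -> float:
    """F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p (0 iff Sigma == S)."""
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if p is None:
        p = S.shape[0]
    if S.shape != sigma.shape or S.shape != (p, p):
        raise ValueError("S and sigma must both be p x p")
    ls = _chol_or_raise(S, "S")
    lsig = _chol_or_raise(sigma, "sigma")
    logdet_s = 2.0 * np.sum(np.log(np.diag(ls)))
    logdet_sig = 2.0 * np.sum(np.log(np.diag(lsig)))
    x = linalg.cho_solve((lsig, True), S)
    f = logdet_sig + np.trace(x) - logdet_s - p
    if f < -1e-8:
        raise FloatingPointError(f"F_ML evaluated to {f}; numerical breakdown")
    return max(f, 0.0)


def _phi_block_discrepancy(phi: np.ndarray, s_exo: np.ndarray) -> float:
    l = _chol_or_raise(phi, "Phi")
    return 2.0 * np.sum(np.log(np.diag(l))) + np.trace(linalg.cho_solve((l, True), s_exo))


def _fit_phi_pattern(
    s_exo: np.ndarray, exo: tuple[str, ...], free_pairs: tuple[tuple[str, str], ...]
) -> tuple[np.ndarray, int, bool, float]:
    """ML estimate of the exogenous covariance block with some off-diagonals free.

    Minimizes ln|Phi| + tr(S Phi^-1) over the pattern. Variances are
    log-transformed to stay positive; starts are sample variances and zero
    covariances. Returns (Phi_hat, iterations, converged, gradient_norm).
    """
    q = len(exo)
    pos = {g: i for i, g in enumerate(exo)}
    pair_idx = [(pos[a], pos[b]) for a, b in free_pairs]

    if not pair_idx:  # diagonal Phi: closed form
        return np.diag(np.diag(s_exo)), 0, True, 0.0
    if len(pair_idx) == q * (q - 1) // 2:  # saturated block: closed form
        return s_exo.copy(), 0, True, 0.0

    def unpack(x: np.ndarray) -> np.ndarray:
        phi = np.zeros((q, q))
        phi[np.diag_indices(q)] = np.exp(x[:q])
        for k, (i, j) in enumerate(pair_idx):
            phi[i, j] = phi[j, i] = x[q + k]
        return phi

    def fun_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        phi = unpack(x)
        try:
            l = linalg.cholesky(phi, lower=True)
        except linalg.LinAlgError:
            # large finite penalty: L-BFGS-B line searches cannot digest inf
            return 1e12, np.zeros_like(x)
        phi_inv = linalg.cho_solve((l, True), np.eye(q))
        f = 2.0 * np.sum(np.log(np.diag(l))) + np.sum(phi_inv * s_exo)
        # dF/dPhi = Phi^-1 - Phi^-1 S Phi^-1 (symmetric)
        g_mat = phi_inv - phi_inv @ s_exo @ phi_inv
        grad = np.empty_like(x)
        grad[:q] = np.diag(g_mat) * np.diag(phi)  # chain rule through log
        for k, (i, j) in enumerate(pair_idx):
            grad[q + k] = 2.0 * g_mat[i, j]
        return f, grad

    x0 = np.concatenate([np.log(np.diag(s_exo)), np.zeros(len(pair_idx))])
    res = optimize.minimize(
        fun_grad, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": MAX_ITER, "gtol": 1e-10, "ftol": 1e-14},
    )
    phi_hat = unpack(res.x)
    gnorm = float(np.linalg.norm(fun_grad(res.x)[1]))
    return phi_hat, int(res.nit), gnorm <= GRADIENT_TOL, gnorm


def fit_model(model: PathModel, moments: SampleMoments) -> FitResult:
    """Fit a recursive SEM by maximum likelihood.

    Each endogenous gene's coefficients and residual variance come from the
    regression of the gene on its parents implied by S (the exact ML solution
    under diagonal Psi); the exogenous block is fit to its covariance
    pattern. Deterministic: same model + moments always give the same fit.
    """
    missing = [g for g in model.genes if g not in moments.labels]
    if missing:
        raise KeyError(f"model genes absent from data: {missing}")
    report = check_identifiability(model)
    if not report.identified:
        raise ValueError("model is not identified (t-rule or recursiveness failed)")
    if moments.n <= model.n_free_parameters:
        warnings.warn(
            f"n={moments.n} does not exceed free parameter count "
            f"t={model.n_free_parameters}; estimates will be unstable",
            stacklevel=2,
        )

    m = moments if moments.labels == model.genes else moments.subset(model.genes)
    S = m.S
    idx = {g: i for i, g in enumerate(model.genes)}

    coeffs: dict[tuple[str, str], float] = {}
    resid: dict[str, float] = {}
    grad_sq = 0.0
    for g in model.endogenous:
        parents = model.parents[g]
        pi = [idx[q] for q in parents]
        gi = idx[g]
        s_pp = S[np.ix_(pi, pi)]
        s_pg = S[pi, gi]
        a = linalg.solve(s_pp, s_pg, assume_a="pos")
        psi = float(S[gi, gi] - s_pg @ a)
        if psi <= 0:  # impossible for PD S, guards numerics
            raise NotPositiveDefiniteError(f"nonpositive residual variance for {g}")
        for q, v in zip(parents, a):
            coeffs[(q, g)] = float(v)
        resid[g] = psi
        grad_sq += float(np.sum(((s_pp @ a - s_pg) * 2.0 / psi) ** 2))

    exo = model.exogenous
    exo_i = [idx[g] for g in exo]
    s_exo = S[np.ix_(exo_i, exo_i)]
    phi_hat, nit, phi_conv, phi_gnorm = _fit_phi_pattern(
        s_exo, exo, model.free_exo_covariances
    )

    theta = ParameterSet(
        path_coefficients=coeffs,
        exo_variances={g: float(phi_hat[i, i]) for i, g in enumerate(exo)},
        exo_covariances={
            (a, b): float(phi_hat[exo.index(a), exo.index(b)])
            for a, b in model.free_exo_covariances
        },
        residual_variances=resid,
    )
    sigma = implied_covariance(model, theta)
    gnorm = math.sqrt(grad_sq + phi_gnorm**2)
    converged = phi_conv and gnorm <= GRADIENT_TOL

    fit = FitResult(
        model=model,
        theta=theta,
        implied_sigma=sigma,
        stats=None,
        converged=converged,
        iterations=nit,
        gradient_norm=gnorm,
        moments=m,
    )
    stats = compute_fit_statistics(fit, m)
    return FitResult(
        model=model,
        theta=theta,
        implied_sigma=sigma,
        stats=stats,
        converged=converged,
        iterations=nit,
        gradient_norm=gnorm,
        moments=m,
    )


def compute_fit_statistics(fit: FitResult, moments: SampleMoments) -> FitStats:
    """Chi-square, GFI family and penalized information criteria for a fit."""
    model = fit.model
    m = moments if moments.labels == model.genes else moments.subset(model.genes)
    S, sigma = m.S, fit.implied_sigma
    p = len(model.genes)
    n = m.n
    t = model.n_free_parameters
    df = p * (p + 1) // 2 - t
    if df < 0:
        raise ValueError(f"negative degrees of freedom ({df}): model over-parameterized")

    f = ml_discrepancy(S, sigma, p)
    chi2 = (n - 1) * f

    w = linalg.solve(sigma, S, assume_a="pos")
    num = np.trace((w - np.eye(p)) @ (w - np.eye(p)))
    den = np.trace(w @ w)
    gfi = float(1.0 - num / den)
    star = p * (p + 1) / 2.0
    agfi = float(1.0 - (star / df) * (1.0 - gfi)) if df > 0 else float("nan")
    pgfi = float((df / star) * gfi)

    ln_n = math.log(n)
    return FitStats(
        f_ml=f, chi_square=chi2, t=t, df=df,
        gfi=gfi, agfi=agfi, pgfi=pgfi,
        aic=chi2 + 2 * t, caic=chi2 + t * (ln_n + 1.0), bic=chi2 + t * ln_n,
    )
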