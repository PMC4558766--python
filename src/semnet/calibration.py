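"""Type-I-error calibration of the delta-BIC acceptance threshold.

A candidate gene that is pure noise should rarely be accepted. The null
distribution of the acceptance statistic is estimated by simulation: each
replicate simulates expression data from the fitted baseline, appends one
random gene (normal, with mean and variance drawn with replacement from a
pool harvested from the population), scans every placement, and records the
best delta BIC. The acceptance threshold is the (1 - alpha) quantile of the
delta-BIC values among *improving* replicates (those whose best placement
beats the baseline at all). The improving fraction itself diagnoses the
baseline: near zero suggests an overfit (saturated) baseline, near one an
underfit baseline improvable by almost any gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .expansion import apply_placement, enumerate_gene_placements, fit_gene_over_placements
from .fit import FitResult, NotPositiveDefiniteError, SampleMoments, fit_model
from .model import PathModel

__all__ = [
    "NullGenePool",
    "CalibrationResult",
    "simulate_from_fit",
    "draw_null_gene",
    "calibrate_bic_threshold",
    "evaluate_null_exceedance",
]

OVERFIT_FRACTION = 0.05
UNDERFIT_FRACTION = 0.95


@dataclass(frozen=True)
class NullGenePool:
    """Per-gene (mean, variance) pairs harvested from an expression matrix."""

    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        means = np.atleast_1d(np.asarray(self.means, dtype=float))
        variances = np.atleast_1d(np.asarray(self.variances, dtype=float))
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "variances", variances)
        if means.shape != variances.shape or means.size == 0:
            raise ValueError("pool needs matching, non-empty mean and variance arrays")
        if np.any(variances <= 0):
            raise ValueError("pool variances must be positive")

    def __len__(self) -> int:
        return self.means.size

    @classmethod
    def from_expression(cls, data: pd.DataFrame) -> "NullGenePool":
        x = data.to_numpy(dtype=float)
        return cls(means=x.mean(axis=0), variances=x.var(axis=0, ddof=1))


@dataclass(frozen=True)
class CalibrationResult:
    reps: int
    improving_fraction: float
    threshold: float
    alpha: float
    null_deltas: np.ndarray  # delta BIC of improving replicates
    diagnostic: Literal["ok", "overfit_suspected", "underfit_suspected"]
    n_failed: int
    seed: int | None
    mode: Literal["improving", "all"]


def simulate_from_fit(
    fit: FitResult,
    means: np.ndarray | None,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw n multivariate-normal samples with covariance Sigma(theta-hat).

    Means default to the sample means stored with the fit. Reproducible:
    the same seed always yields the same matrix.
    """
    p = len(fit.model.genes)
    if n < p + 1:
        raise ValueError(f"n={n} must exceed the number of variables p={p}")
    if means is None:
        if fit.moments is None:
            raise ValueError("no means supplied and none stored with the fit")
        means = fit.moments.means
    means = np.asarray(means, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    try:
        chol = np.linalg.cholesky(fit.implied_sigma)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError("implied covariance of the fit is not PD") from None
    z = rng.standard_normal((n, p))
    return pd.DataFrame(means + z @ chol.T, columns=list(fit.model.genes))


def draw_null_gene(
    pool: NullGenePool, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """One random gene: n iid normal draws with pool-sampled mean and variance."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = rng.integers(len(pool))
    return rng.normal(pool.means[k], np.sqrt(pool.variances[k]), size=n)


def _null_replicate_deltas(
    model: PathModel,
    base_fit: FitResult,
    pool: NullGenePool,
    n: int,
    reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Best delta BIC of one appended null gene, per simulated replicate."""
    placements = enumerate_gene_placements(model)
    placeholder = "__null__"
    prebuilt = [apply_placement(model, placeholder, pl) for pl in placements]
    ref_model = model.with_gene(placeholder)
    labels = tuple(model.genes) + (placeholder,)
    deltas = np.empty(reps)
    n_failed = 0
    for r in range(reps):
        sub = np.random.default_rng(rng.integers(2**31))
        sim = simulate_from_fit(base_fit, None, n, sub)
        gene = draw_null_gene(pool, n, sub)
        x = np.column_stack([sim.to_numpy(), gene])
        try:
            moments = SampleMoments(
                S=np.cov(x, rowvar=False, ddof=1),
                means=x.mean(axis=0), n=n, labels=labels,
            )
            _, best, base_bic = fit_gene_over_placements(
                model, moments, placeholder, placements, threshold=np.inf,
                placement_models=prebuilt, reference_model=ref_model,
            )
        except NotPositiveDefiniteError:
            deltas[r] = np.nan
            n_failed += 1
            continue
        if best is None:
            deltas[r] = np.nan
            n_failed += 1
        else:
            deltas[r] = base_bic - best.bic
    return deltas, n_failed


def calibrate_bic_threshold(
    model: PathModel,
    data: SampleMoments,
    pool: NullGenePool,
    reps: int = 8000,
    alpha: float = 0.05,
    seed: int | None = None,
    mode: Literal["improving", "all"] = "improving",
) -> CalibrationResult:
    """Simulate the null delta-BIC distribution and set the acceptance threshold.

    ``mode="improving"`` (default) takes the (1 - alpha) quantile over
    replicates whose best placement improved on the baseline;
    ``mode="all"`` takes it over every replicate (non-improvers contribute
    their non-positive delta). If no replicate improves the threshold is 0
    and the baseline is flagged as possibly overfit.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    base_fit = fit_model(model, data)
    if not base_fit.converged:
        raise RuntimeError("baseline fit did not converge; cannot calibrate")
    rng = np.random.default_rng(seed)
    deltas, n_failed = _null_replicate_deltas(model, base_fit, pool, data.n, reps, rng)
    if n_failed > 0.1 * reps:
        raise RuntimeError(
            f"{n_failed}/{reps} calibration replicates failed to fit; aborting"
        )
    valid = deltas[~np.isnan(deltas)]
    improving = valid[valid > 0]
    improving_fraction = improving.size / max(valid.size, 1)

    if improving.size == 0:
        threshold = 0.0
    elif mode == "improving":
        threshold = float(np.quantile(improving, 1.0 - alpha))
    else:
        threshold = float(max(np.quantile(valid, 1.0 - alpha), 0.0))

    if improving_fraction <= OVERFIT_FRACTION:
        diagnostic = "overfit_suspected"
    elif improving_fraction >= UNDERFIT_FRACTION:
        diagnostic = "underfit_suspected"
    else:
        diagnostic = "ok"
    return CalibrationResult(
        reps=reps, improving_fraction=float(improving_fraction),
        threshold=max(threshold, 0.0), alpha=alpha, null_deltas=improving,
        diagnostic=diagnostic, n_failed=n_failed, seed=seed, mode=mode,
    )


def evaluate_null_exceedance(
    model: PathModel,
    data: SampleMoments,
    pool: NullGenePool,
    threshold: float,
    reps: int = 2000,
    seed: int | None = None,
) -> tuple[float, int]:
    """Empirical type-I check: fraction of fresh improving null replicates
    whose delta BIC exceeds the threshold. Returns (fraction, n_improving)."""
    base_fit = fit_model(model, data)
    rng = np.random.default_rng(seed)
    deltas, _ = _null_replicate_deltas(model, base_fit, pool, data.n, reps, rng)
    improving = deltas[np.isfinite(deltas) & (deltas > 0)]
    if improving.size == 0:
        return 0.0, 0
    return float(np.mean(improving > threshold)), int(improving.size)
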