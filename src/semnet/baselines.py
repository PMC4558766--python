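"""Literature-derived baseline models of the Drosophila sex-determination hierarchy.

The splicing cascade Sxl -> tra -> dsx/fru (with the cofactors Spf45, snf,
vir, fl(2)d, tra2 and the downstream modifiers her and ix) terminates in the
yolk-protein readout Yp2. Two population-specific baselines are provided:

* ``cegs`` — 12 genes, 14 paths (dsx measured; dsx -> Yp2 branch present).
* ``dspr`` — 11 genes, 13 paths (dsx not measured; tra/tra2 wired directly
  to Yp2 to preserve the readout).

Each baseline comes in three exogenous-covariance variants: ``none`` (all
phi fixed to 0), ``full`` (all pairs free), and ``partial`` (only the
empirically co-varying tra2 ~~ snf, tra2 ~~ Spf45, tra2 ~~ fl(2)d pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import pandas as pd

from .fit import SampleMoments, fit_model
from .model import PathModel

__all__ = ["BaselineConfig", "build_baseline", "compare_covariance_structures"]

_CEGS_GENES = (
    "Spf45", "snf", "vir", "fl(2)d", "tra2", "her", "ix",
    "Sxl", "tra", "fru", "dsx", "Yp2",
)

_CEGS_PATHS = (
    ("Spf45", "Sxl"), ("snf", "Sxl"), ("vir", "Sxl"), ("fl(2)d", "Sxl"),
    ("Sxl", "tra"), ("vir", "tra"), ("fl(2)d", "tra"),
    ("tra", "fru"), ("tra2", "fru"),
    ("tra", "dsx"), ("tra2", "dsx"),
    ("dsx", "Yp2"), ("her", "Yp2"), ("ix", "Yp2"),
)

# dsx unmeasured: drop its branch, wire the tra/tra2 splice regulators
# straight to the readout so Yp2 stays endogenous.
_DSPR_GENES = tuple(g for g in _CEGS_GENES if g != "dsx")
_DSPR_PATHS = tuple(p for p in _CEGS_PATHS if "dsx" not in p) + (
    ("tra", "Yp2"), ("tra2", "Yp2"),
)

_PARTIAL_PAIRS = (("tra2", "snf"), ("tra2", "Spf45"), ("tra2", "fl(2)d"))

Population = Literal["dspr", "cegs"]
CovarianceVariant = Literal["full", "none", "partial"]


@dataclass(frozen=True)
class BaselineConfig:
    population: Population
    covariance_variant: CovarianceVariant = "none"

    def __post_init__(self) -> None:
        if self.population not in ("dspr", "cegs"):
            raise ValueError(f"unknown population {self.population!r}")
        if self.covariance_variant not in ("full", "none", "partial"):
            raise ValueError(f"unknown covariance variant {self.covariance_variant!r}")


def build_baseline(config: BaselineConfig | None = None, **kwargs) -> PathModel:
    """Construct a sex-hierarchy baseline :class:`PathModel`.

    ``build_baseline(BaselineConfig("cegs", "none"))`` or, for convenience,
    ``build_baseline(population="cegs", covariance_variant="none")``.
    """
    if config is None:
        config = BaselineConfig(**kwargs)
    genes = _CEGS_GENES if config.population == "cegs" else _DSPR_GENES
    paths = _CEGS_PATHS if config.population == "cegs" else _DSPR_PATHS

    exo = tuple(g for g in genes if g not in {t for _, t in paths})
    if config.covariance_variant == "none":
        covs: tuple[tuple[str, str], ...] = ()
    elif config.covariance_variant == "full":
        covs = tuple(combinations(exo, 2))
    else:
        covs = _PARTIAL_PAIRS
    return PathModel(genes=genes, paths=paths, free_exo_covariances=covs, reporter="Yp2")


def compare_covariance_structures(
    data: SampleMoments, population: Population
) -> pd.DataFrame:
    """Fit the full / none / partial covariance baselines and tabulate fit.

    Returns one row per variant with AGFI, PGFI, CAIC and BIC plus a
    ``winner`` marker column per statistic (AGFI/PGFI maximized, CAIC/BIC
    minimized). Fit failures are reported in an ``error`` column rather than
    aborting the whole comparison.
    """
    rows = []
    for variant in ("full", "none", "partial"):
        model = build_baseline(BaselineConfig(population, variant))
        try:
            fit = fit_model(model, data)
            s = fit.stats
            rows.append(
                {"variant": variant, "AGFI": s.agfi, "PGFI": s.pgfi,
                 "CAIC": s.caic, "BIC": s.bic, "converged": fit.converged,
                 "error": ""}
            )
        except Exception as exc:  # propagate per-row, keep the table
            rows.append(
                {"variant": variant, "AGFI": float("nan"), "PGFI": float("nan"),
                 "CAIC": float("nan"), "BIC": float("nan"), "converged": False,
                 "error": str(exc)}
            )
    table = pd.DataFrame(rows).set_index("variant")
    winners = {
        "AGFI": table["AGFI"].idxmax(skipna=True),
        "PGFI": table["PGFI"].idxmax(skipna=True),
        "CAIC": table["CAIC"].idxmin(skipna=True),
        "BIC": table["BIC"].idxmin(skipna=True),
    }
    table.attrs["winners"] = winners
    return table
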