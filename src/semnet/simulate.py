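"""Ground-truth synthetic data: GRN expression, candidate pools, genotype fixtures.

Two named regimes mirror the mapping populations the method targets:
``dspr-like`` (n = 596 microarray-style samples, no dsx) and ``cegs-like``
(n = 75 RNA-seq-style samples, dsx measured). Expression is multivariate
normal, drawn from the structural equations themselves — exogenous genes
from N(0, Phi), residuals from N(0, Psi), endogenous genes by solving
eta = B eta + Gamma xi + zeta — so the generating parameters are the exact
ground truth for recovery tests. Default generating values are moderate
regulatory strength (all path coefficients 0.5) with unit variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import BaselineConfig, build_baseline
from .fit import FitResult
from .model import ParameterSet, PathModel, topological_order

__all__ = [
    "SimulationConfig",
    "CandidateSpec",
    "AlleleFixture",
    "default_parameters",
    "generate_grn_dataset",
    "generate_candidate_pool",
    "simulate_population",
    "parameter_recovery_report",
    "generate_allele_fixture",
]

REGIMES = {"dspr-like": ("dspr", 596), "cegs-like": ("cegs", 75)}
DEFAULT_COEFFICIENT = 0.5
# log2-expression-scale pool for null candidate genes
DEFAULT_MEAN_RANGE = (2.0, 12.0)
DEFAULT_VAR_RANGE = (0.25, 4.0)


@dataclass(frozen=True)
class CandidateSpec:
    """A true candidate gene: child of one pathway parent with known effect."""

    name: str
    parent: str
    coefficient: float = 0.8
    noise_variance: float = 0.36
    mean: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    model: PathModel
    parameters: ParameterSet
    n: int
    means: dict[str, float] = field(default_factory=dict)
    true_candidates: tuple[CandidateSpec, ...] = ()
    n_null_candidates: int = 0
    mean_range: tuple[float, float] = DEFAULT_MEAN_RANGE
    var_range: tuple[float, float] = DEFAULT_VAR_RANGE
    seed: int | None = None

    def __post_init__(self) -> None:
        self.parameters.validate_against(self.model)
        # candidates are scanned one at a time, so the largest model ever fit
        # holds the pathway genes plus one candidate
        has_cand = bool(self.true_candidates) or self.n_null_candidates > 0
        total = len(self.model.genes) + (1 if has_cand else 0)
        if self.n < 2 * total:
            raise ValueError(
                f"n={self.n} too small for {total} jointly modeled variables "
                f"(need >= {2 * total})"
            )


def default_parameters(
    model: PathModel,
    coefficient: float = DEFAULT_COEFFICIENT,
    exo_variance: float = 1.0,
    residual_variance: float = 1.0,
    exo_covariance: float = 0.0,
) -> ParameterSet:
    """Uniform generating values for every free parameter of a model."""
    return ParameterSet(
        path_coefficients={p: coefficient for p in model.paths},
        exo_variances={g: exo_variance for g in model.exogenous},
        exo_covariances={p: exo_covariance for p in model.free_exo_covariances},
        residual_variances={g: residual_variance for g in model.endogenous},
    )


def generate_grn_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict]:
    """Draw expression from the structural equations; return (data, truth).

    The truth record carries every generating parameter (flat name -> value),
    the model edge list, and the seed, so recovery can be audited parameter
    by parameter.
    """
    model, theta = config.model, config.parameters
    rng = np.random.default_rng(config.seed)
    genes = model.genes
    idx = {g: i for i, g in enumerate(genes)}
    p = len(genes)

    exo = model.exogenous
    q = len(exo)
    phi = np.zeros((q, q))
    for i, g in enumerate(exo):
        phi[i, i] = theta.exo_variances[g]
    pos = {g: i for i, g in enumerate(exo)}
    for (a, b), v in theta.exo_covariances.items():
        phi[pos[a], pos[b]] = phi[pos[b], pos[a]] = v
    chol = np.linalg.cholesky(phi)  # raises if Phi not PD

    x = np.zeros((config.n, p))
    xi = rng.standard_normal((config.n, q)) @ chol.T
    for g in exo:
        x[:, idx[g]] = xi[:, pos[g]]
    for g in topological_order(model):
        if g in theta.residual_variances:
            zeta = rng.normal(0.0, np.sqrt(theta.residual_variances[g]), config.n)
            val = zeta.copy()
            for parent in model.parents[g]:
                val += theta.path_coefficients[(parent, g)] * x[:, idx[parent]]
            x[:, idx[g]] = val
    for g, mu in config.means.items():
        x[:, idx[g]] += mu

    data = pd.DataFrame(x, columns=list(genes))
    truth = {
        "parameters": theta.as_flat_dict(),
        "paths": [list(e) for e in model.paths],
        "means": dict(config.means),
        "n": config.n,
        "seed": config.seed,
    }
    return data, truth


def generate_candidate_pool(
    config: SimulationConfig,
    pathway_data: pd.DataFrame,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Candidate columns for the pathway samples: planted true genes plus nulls.

    True candidates are linear children of their specified parent; null
    candidates are iid normal with moments drawn uniformly from the
    configured ranges. Labels map column -> {"true", "null"}.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(pathway_data)
    cols: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for spec in config.true_candidates:
        parent = pathway_data[spec.parent].to_numpy()
        cols[spec.name] = (
            spec.mean
            + spec.coefficient * (parent - parent.mean())
            + rng.normal(0.0, np.sqrt(spec.noise_variance), n)
        )
        labels[spec.name] = "true"
    for k in range(config.n_null_candidates):
        name = f"null_{k:04d}"
        mu = rng.uniform(*config.mean_range)
        var = rng.uniform(*config.var_range)
        cols[name] = rng.normal(mu, np.sqrt(var), n)
        labels[name] = "null"
    frame = pd.DataFrame(cols, index=pathway_data.index)
    if len(set(frame.columns)) != frame.shape[1]:
        raise ValueError("candidate labels collide")
    return frame, labels


def simulate_population(
    regime: str = "cegs-like",
    n: int | None = None,
    n_null_candidates: int = 0,
    true_candidates: tuple[CandidateSpec, ...] = (),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationConfig, dict]:
    """One-call study-condition generator.

    Builds the regime's no-covariance baseline with the default generating
    parameters and sample size (596 for dspr-like, 75 for cegs-like),
    returning (pathway data, candidate data, config, truth).
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(REGIMES)}")
    population, default_n = REGIMES[regime]
    model = build_baseline(BaselineConfig(population, "none"))
    config = SimulationConfig(
        model=model,
        parameters=default_parameters(model),
        n=n if n is not None else default_n,
        true_candidates=true_candidates,
        n_null_candidates=n_null_candidates,
        seed=seed,
    )
    data, truth = generate_grn_dataset(config)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    candidates, labels = generate_candidate_pool(config, data, rng)
    truth["candidate_labels"] = labels
    return data, candidates, config, truth


def parameter_recovery_report(
    truth: ParameterSet | dict, fit: FitResult
) -> pd.DataFrame:
    """Per-parameter (true, estimated, bias, relative error) plus RMSE.

    ``truth`` is a ParameterSet or a flat dict as written by
    :func:`generate_grn_dataset`. Aggregate RMSE is stored in
    ``frame.attrs["rmse"]``; mean absolute relative error in
    ``frame.attrs["mean_relative_error"]``.
    """
    true_flat = truth.as_flat_dict() if isinstance(truth, ParameterSet) else dict(truth)
    est_flat = fit.theta.as_flat_dict()
    if set(true_flat) != set(est_flat):
        raise ValueError("truth and fit have different parameter structures")
    rows = []
    for name in sorted(true_flat):
        tv, ev = true_flat[name], est_flat[name]
        rows.append({
            "parameter": name, "true": tv, "estimated": ev, "bias": ev - tv,
            "relative_error": abs(ev - tv) / abs(tv) if tv != 0 else float("inf"),
        })
    frame = pd.DataFrame(rows).set_index("parameter")
    frame.attrs["rmse"] = float(np.sqrt(np.mean(frame["bias"] ** 2)))
    frame.attrs["mean_relative_error"] = float(frame["relative_error"].mean())
    return frame


@dataclass(frozen=True)
class AlleleFixture:
    """A toy multi-sample VCF + CDS BED with hand-enumerable allele counts."""

    vcf_text: str
    bed_text: str
    expected_counts: dict[str, int]
    samples: tuple[str, ...]

    def write(self, directory: str | Path) -> tuple[Path, Path]:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        vcf = d / "synthetic_variants.vcf"
        bed = d / "synthetic_cds.bed"
        vcf.write_text(self.vcf_text)
        bed.write_text(self.bed_text)
        return vcf, bed


def generate_allele_fixture(seed: int = 0, n_samples: int = 6) -> AlleleFixture:
    """Small synthetic VCF 4.2 + BED6 fixture with known haplotype counts.

    Three genes on one contig: geneA has two biallelic SNPs with shared
    haplotypes, geneB has no variable site (expected count 1), geneC has
    enough variation that every sample is distinct (count = n_samples).
    The expected counts are computed here by direct enumeration of the
    generated haplotype strings, independent of any VCF-reading code.
    """
    rng = np.random.default_rng(seed)
    samples = tuple(f"line{i + 1}" for i in range(n_samples))

    # gene intervals, BED half-open 0-based
    genes = {"geneA": (100, 200), "geneB": (300, 400), "geneC": (500, 620)}

    records = []  # (pos1based, ref, alt, gene, genotypes 0/1)
    # geneA: 2 sites, haplotypes drawn from 2 patterns
    pat = rng.integers(0, 2, size=n_samples)  # which of two haplotypes
    hapA = [(0, 1), (1, 0)]
    for k, pos in enumerate((120, 180)):
        gts = [hapA[p][k] for p in pat]
        records.append((pos + 1, "A", "T", "geneA", gts))
    # geneC: ceil(log2 n) sites encoding each sample uniquely
    n_sites = max(1, int(np.ceil(np.log2(n_samples))))
    for k in range(n_sites):
        pos = 520 + 10 * k
        gts = [(i >> k) & 1 for i in range(n_samples)]
        records.append((pos + 1, "G", "C", "geneC", gts))

    expected = {}
    for gene in genes:
        haps = []
        for i in range(n_samples):
            haps.append(
                "".join(str(gts[i]) for _, _, _, g, gts in records if g == gene)
            )
        expected[gene] = len(set(haps))

    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr2L,length=23513712>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )
    body = ""
    for pos, ref, alt, _, gts in sorted(records):
        row = [
            "chr2L", str(pos), ".", ref, alt, "60", "PASS", ".", "GT",
        ] + [str(g) for g in gts]
        body += "\t".join(row) + "\n"

    bed = ""
    for gene, (start, end) in genes.items():
        bed += f"chr2L\t{start}\t{end}\t{gene}\t0\t+\n"

    return AlleleFixture(header + body, bed, expected, samples)
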