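"""File formats, the model-spec grammar, normalization and validation utilities.

Model-spec grammar (one statement per line, ``#`` comments allowed)::

    gene Sxl
    gene tra
    path Sxl -> tra
    cov tra2 ~~ snf
    reporter Yp2

Expression matrices are TSV with a header row; the first column holds sample
identifiers when samples are rows (``orientation="samples_by_genes"``) or
gene identifiers when genes are rows (``orientation="genes_by_samples"``).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import contingency, fisher_exact

from .fit import SampleMoments
from .model import ModelSpecError, PathModel

__all__ = [
    "parse_model_spec",
    "render_model_spec",
    "read_model_spec",
    "read_expression_matrix",
    "uq_log_normalize",
    "read_de_table",
    "de_overlap",
    "fisher_enrichment",
    "count_alleles",
]


def parse_model_spec(text: str) -> PathModel:
    """Parse the line-based model grammar into a :class:`PathModel`.

    Exogenous/endogenous status is inferred from the path statements; errors
    cite the offending line number.
    """
    genes: list[str] = []
    paths: list[tuple[str, str]] = []
    covs: list[tuple[str, str]] = []
    reporter: str | None = None

    def err(lineno: int, msg: str) -> ModelSpecError:
        return ModelSpecError(f"line {lineno}: {msg}")

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        kw = tokens[0]
        if kw == "gene":
            if len(tokens) != 2:
                raise err(lineno, f"expected 'gene <id>', got {raw.strip()!r}")
            if tokens[1] in genes:
                raise err(lineno, f"duplicate gene {tokens[1]}")
            genes.append(tokens[1])
        elif kw == "path":
            if len(tokens) != 4 or tokens[2] != "->":
                raise err(lineno, f"expected 'path <src> -> <dst>', got {raw.strip()!r}")
            src, dst = tokens[1], tokens[3]
            for g in (src, dst):
                if g not in genes:
                    raise err(lineno, f"path references undeclared gene {g}")
            if src == dst:
                raise err(lineno, f"self-loop {src} -> {src} is not allowed")
            if (src, dst) in paths:
                raise err(lineno, f"duplicate path {src} -> {dst}")
            paths.append((src, dst))
        elif kw == "cov":
            if len(tokens) != 4 or tokens[2] != "~~":
                raise err(lineno, f"expected 'cov <a> ~~ <b>', got {raw.strip()!r}")
            a, b = tokens[1], tokens[3]
            for g in (a, b):
                if g not in genes:
                    raise err(lineno, f"cov references undeclared gene {g}")
            covs.append((a, b))
        elif kw == "reporter":
            if len(tokens) != 2:
                raise err(lineno, f"expected 'reporter <id>', got {raw.strip()!r}")
            if tokens[1] not in genes:
                raise err(lineno, f"reporter references undeclared gene {tokens[1]}")
            reporter = tokens[1]
        else:
            raise err(lineno, f"unknown statement {kw!r}")
    try:
        return PathModel(tuple(genes), tuple(paths), tuple(covs), reporter)
    except ModelSpecError:
        raise
    except Exception as exc:  # keep parse-time failures uniform
        raise ModelSpecError(str(exc)) from exc


def render_model_spec(model: PathModel) -> str:
    """Inverse of :func:`parse_model_spec` (round-trips up to whitespace)."""
    lines = [f"gene {g}" for g in model.genes]
    lines += [f"path {s} -> {t}" for s, t in model.paths]
    lines += [f"cov {a} ~~ {b}" for a, b in model.free_exo_covariances]
    if model.reporter is not None:
        lines.append(f"reporter {model.reporter}")
    return "\n".join(lines) + "\n"


def read_model_spec(path: str | Path) -> PathModel:
    return parse_model_spec(Path(path).read_text())


def read_expression_matrix(
    path: str | Path, orientation: str = "samples_by_genes"
) -> tuple[pd.DataFrame, SampleMoments]:
    """Read a TSV expression matrix; return (samples x genes frame, moments).

    Missing values are a hard error (no imputation); duplicate sample or
    gene identifiers are rejected.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "genes_by_samples":
        frame = frame.T
    elif orientation != "samples_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    frame.columns = frame.columns.map(str)
    frame.index = frame.index.map(str)
    if frame.index.duplicated().any():
        raise ValueError("duplicate sample identifiers")
    if frame.columns.duplicated().any():
        raise ValueError("duplicate gene identifiers")
    if frame.isna().any().any():
        bad = list(frame.columns[frame.isna().any()])
        raise ValueError(f"missing values in columns {bad}; imputation is not supported")
    return frame, SampleMoments.from_data(frame)


def uq_log_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Upper-quartile normalization then log2(x + 1), per sample (rows).

    Each sample's counts are scaled by (mean upper quartile across samples) /
    (that sample's upper quartile over its expressed genes), putting samples
    on a common scale before the log transform.
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    uq = np.empty(x.shape[0])
    for i, row in enumerate(x):
        expressed = row[row > 0]
        if expressed.size == 0:
            raise ValueError(f"sample {counts.index[i]!r} has no expressed genes")
        uq[i] = np.percentile(expressed, 75)
    if (uq <= 0).any():
        raise ValueError("each sample needs a positive upper quartile")
    scaled = x * (uq.mean() / uq)[:, None]
    return pd.DataFrame(np.log2(scaled + 1.0), index=counts.index, columns=counts.columns)


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Differential-expression table: gene, fdr_cmp1, dir_cmp1, fdr_cmp2, dir_cmp2."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"gene", "fdr_cmp1", "dir_cmp1", "fdr_cmp2", "dir_cmp2"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    for col in ("fdr_cmp1", "fdr_cmp2"):
        if ((frame[col] < 0) | (frame[col] > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    for col in ("dir_cmp1", "dir_cmp2"):
        if not frame[col].isin(["+", "-"]).all():
            raise ValueError(f"{col} must be '+' or '-'")
    return frame.set_index("gene")


def de_overlap(
    expansion_genes: list[str] | set[str],
    de_table: pd.DataFrame,
    fdr_cutoff: float,
    require_same_direction: bool = True,
) -> pd.DataFrame:
    """Expansion genes that are differentially expressed in both comparisons.

    A gene qualifies when both comparison FDRs are at or below the cutoff
    and (optionally) the fold-change directions agree. The cutoff has no
    default: the two published control comparisons used different values, so
    the caller must choose.
    """
    de = de_table
    ok = (de["fdr_cmp1"] <= fdr_cutoff) & (de["fdr_cmp2"] <= fdr_cutoff)
    if require_same_direction:
        ok &= de["dir_cmp1"] == de["dir_cmp2"]
    hits = de[ok & de.index.isin(set(expansion_genes))]
    return hits.assign(direction=hits["dir_cmp1"]).sort_index()


def fisher_enrichment(
    hits: set[str], annotated: set[str], universe: set[str]
) -> tuple[float, float]:
    """Two-sided Fisher's exact test for annotation enrichment among hits.

    Returns (conditional-MLE odds ratio, exact two-sided p-value) for the
    2x2 table (in/out of hits) x (in/out of annotated) over the universe.
    """
    hits, annotated, universe = set(hits), set(annotated), set(universe)
    if not universe:
        raise ValueError("universe is empty")
    if not hits <= universe or not annotated <= universe:
        raise ValueError("hits and annotated must be subsets of the universe")
    a = len(hits & annotated)
    b = len(hits - annotated)
    c = len(annotated - hits)
    d = len(universe) - a - b - c
    table = [[a, b], [c, d]]
    _, p = fisher_exact(table, alternative="two-sided")
    odds = contingency.odds_ratio(table, kind="conditional").statistic
    return float(odds), float(p)


def _read_bed6(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """BED6 with the gene identifier in the name field -> gene -> intervals
    (0-based half-open, as in the file)."""
    genes: dict[str, list[tuple[str, int, int]]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}: line {lineno} has fewer than 4 BED fields")
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        if end <= start:
            raise ValueError(f"{path}: line {lineno}: empty interval {start}-{end}")
        genes.setdefault(name, []).append((chrom, start, end))
    return genes


def count_alleles(
    vcf_path: str | Path,
    bed_path: str | Path,
    mode: str = "reference",
) -> tuple[dict[str, int], dict[str, int]]:
    """Count distinct SNP haplotypes per gene across CDS intervals.

    Each sample's allele string concatenates its calls at every variant
    position overlapping the gene's CDS intervals; the allele count is the
    number of distinct strings (>= 1 even with no variable site). Modes:

    * ``reference`` — missing genotype calls are assumed homozygous reference.
    * ``maf_drop`` — sites with minor-allele frequency < 5% are dropped, then
      samples with remaining missing calls are dropped for that gene.

    VCF positions (1-based) are converted to the BED half-open 0-based system
    internally. Indel records are skipped and tallied. Returns
    (gene -> allele count, info counters including ``indels_skipped``).
    Genes with no CDS interval in the BED are simply absent from the result.
    """
    from cyvcf2 import VCF
    from intervaltree import IntervalTree

    if mode not in ("reference", "maf_drop"):
        raise ValueError(f"unknown mode {mode!r}")
    gene_intervals = _read_bed6(bed_path)
    trees: dict[str, IntervalTree] = {}
    for gene, ivs in gene_intervals.items():
        for chrom, start, end in ivs:
            trees.setdefault(chrom, IntervalTree()).addi(start, end, gene)

    vcf = VCF(str(vcf_path), gts012=True)
    samples = vcf.samples
    n = len(samples)
    if n == 0:
        raise ValueError("VCF has no samples")

    # gene -> list of per-sample call codes per site: 0 ref, 1 alt, -1 missing
    site_calls: dict[str, list[np.ndarray]] = {g: [] for g in gene_intervals}
    info = {"indels_skipped": 0, "het_calls_first_allele": 0, "sites_used": 0}
    for variant in vcf:
        if not variant.is_snp:
            info["indels_skipped"] += 1
            continue
        tree = trees.get(variant.CHROM)
        if tree is None:
            continue
        pos0 = variant.POS - 1  # VCF 1-based -> 0-based
        overlapping = tree[pos0]
        if not overlapping:
            continue
        calls = np.empty(n, dtype=int)
        n_het = 0
        for i, g in enumerate(variant.genotypes):
            alleles = [int(a) for a in g[:-1]]  # last entry is the phase flag
            calls[i] = alleles[0]  # -1 encodes a missing call
            if len({a for a in alleles if a >= 0}) > 1:
                n_het += 1
        if n_het:
            info["het_calls_first_allele"] += n_het
            warnings.warn(
                f"{n_het} heterozygous calls at {variant.CHROM}:{variant.POS} "
                "counted by their first allele (inbred/hemizygous lines expected)",
                stacklevel=2,
            )
        info["sites_used"] += 1
        for iv in overlapping:
            site_calls[iv.data].append(calls)

    counts: dict[str, int] = {}
    for gene, sites in site_calls.items():
        if not sites:
            counts[gene] = 1
            continue
        mat = np.stack(sites, axis=1)  # samples x sites
        if mode == "reference":
            mat = np.where(mat == -1, 0, mat)
            keep_samples = np.ones(n, dtype=bool)
        else:
            filled = np.where(mat == -1, 0, mat)
            alt_freq = (filled > 0).mean(axis=0)
            maf = np.minimum(alt_freq, 1.0 - alt_freq)
            mat = mat[:, maf >= 0.05]
            keep_samples = ~(mat == -1).any(axis=1)
            mat = mat[keep_samples]
        if mat.size == 0:
            counts[gene] = 1
            continue
        haplotypes = {tuple(row) for row in mat}
        counts[gene] = max(len(haplotypes), 1)
    return counts, info
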