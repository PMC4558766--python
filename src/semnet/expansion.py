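"""Exhaustive single-addition model scans: new paths and candidate-gene placements.

Every candidate model differs from the baseline by exactly one addition —
either a new directed path between two pathway genes, or one outside gene
wired in at one placement (upstream of a gene, downstream of a gene, or
inserted along an existing edge). Fit improvement is measured by
delta BIC = BIC(baseline) - BIC(candidate); additions are accepted when
delta BIC exceeds a threshold, typically calibrated by null-gene simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .fit import FitResult, SampleMoments, fit_model
from .model import NonRecursiveModelError, PathModel

__all__ = [
    "Placement",
    "ScanRecord",
    "GeneScanResult",
    "OverlapReport",
    "enumerate_new_paths",
    "enumerate_gene_placements",
    "apply_placement",
    "scan_new_paths",
    "scan_candidate_genes",
    "intersect_scans",
]

PlacementKind = Literal["upstream", "downstream", "insertion"]


@dataclass(frozen=True)
class Placement:
    """One way to wire a candidate gene into the baseline.

    * ``upstream``: gene -> anchor (gene enters as a new exogenous variable).
    * ``downstream``: anchor -> gene (gene enters endogenous; the reporter is
      never a downstream anchor).
    * ``insertion``: src -> gene -> dst along a baseline edge; the direct
      src -> dst path is retained so the candidate model nests the baseline.
    """

    kind: PlacementKind
    anchor: str | tuple[str, str]
    model_index: int  # 1-based position in the deterministic enumeration

    def describe(self) -> str:
        if self.kind == "upstream":
            return f"gene->{self.anchor}"
        if self.kind == "downstream":
            return f"{self.anchor}->gene"
        src, dst = self.anchor
        return f"{src}->gene->{dst}"


@dataclass(frozen=True)
class ScanRecord:
    """One candidate model and its BIC comparison against the baseline."""

    candidate: tuple[str, str] | tuple[str, Placement]
    bic: float
    delta_bic: float
    converged: bool
    accepted: bool
    skipped_reason: str | None = None
    model_index: int | None = None


@dataclass(frozen=True)
class GeneScanResult:
    """Per-gene summary plus the full placement-level records."""

    summary: pd.DataFrame
    records: dict[str, list[ScanRecord]]
    threshold: float
    n_models_evaluated: int

    @property
    def accepted_genes(self) -> list[str]:
        return list(self.summary.index[self.summary["accepted"]])


def enumerate_new_paths(model: PathModel) -> list[tuple[str, str]]:
    """All ordered gene pairs not already a path and not a path reversal.

    A reversal of an existing edge would close a 2-cycle with it, breaking
    recursiveness, so both directions of every baseline edge are excluded:
    count = G(G-1) - 2E.
    """
    existing = set(model.paths)
    blocked = existing | {(t, s) for s, t in existing}
    return [
        (a, b)
        for a in model.genes
        for b in model.genes
        if a != b and (a, b) not in blocked
    ]


def enumerate_gene_placements(model: PathModel) -> list[Placement]:
    """All single-gene placements: (G-1) downstream + G upstream + E insertions.

    Downstream placements anchor on every gene except the reporter (the
    terminal readout is never a regulator source); upstream placements anchor
    on every gene; insertions follow edge declaration order. Ordering is
    deterministic: downstream over endogenous-then-exogenous genes, then
    upstream likewise, then insertions.
    """
    if model.reporter is None:
        raise ValueError("gene placement enumeration requires a reporter gene")
    gene_order = list(model.endogenous) + list(model.exogenous)
    placements: list[Placement] = []
    i = 1
    for g in gene_order:
        if g == model.reporter:
            continue
        placements.append(Placement("downstream", g, i))
        i += 1
    for g in gene_order:
        placements.append(Placement("upstream", g, i))
        i += 1
    for edge in model.paths:
        placements.append(Placement("insertion", edge, i))
        i += 1
    return placements


def apply_placement(model: PathModel, gene: str, placement: Placement) -> PathModel:
    """Baseline plus one candidate gene wired per the placement."""
    if placement.kind == "upstream":
        return model.with_gene(gene, [(gene, placement.anchor)])
    if placement.kind == "downstream":
        return model.with_gene(gene, [(placement.anchor, gene)])
    src, dst = placement.anchor
    if (src, dst) not in model.paths:
        raise ValueError(f"insertion anchor {src}->{dst} is not a baseline edge")
    return model.with_gene(gene, [(src, gene), (gene, dst)])


def _isolated_gene_model(model: PathModel, gene: str) -> PathModel:
    """Baseline augmented with the candidate gene as an isolated exogenous
    variable (free variance, no paths): the reference model that makes BICs
    comparable across the enlarged variable set."""
    return model.with_gene(gene)


def scan_new_paths(
    model: PathModel,
    data: SampleMoments,
    threshold: float,
    baseline_fit: FitResult | None = None,
) -> list[ScanRecord]:
    """Fit baseline + each candidate path; accept when delta BIC > threshold.

    Candidates that would make the model non-recursive (close a directed
    cycle) are recorded as skipped with the reason, never silently dropped.
    Records are sorted by delta BIC descending, skipped candidates last.
    """
    if baseline_fit is None:
        baseline_fit = fit_model(model, data)
    base_bic = baseline_fit.stats.bic
    records: list[ScanRecord] = []
    for src, dst in enumerate_new_paths(model):
        try:
            cand = model.with_path(src, dst)
        except NonRecursiveModelError as exc:
            records.append(
                ScanRecord((src, dst), float("nan"), float("nan"),
                           False, False, skipped_reason=str(exc))
            )
            continue
        fit = fit_model(cand, data)
        delta = base_bic - fit.stats.bic
        records.append(
            ScanRecord((src, dst), fit.stats.bic, delta,
                       fit.converged, fit.converged and delta > threshold)
        )
    records.sort(key=lambda r: (-np.inf if np.isnan(r.delta_bic) else r.delta_bic),
                 reverse=True)
    return records


def fit_gene_over_placements(
    model: PathModel,
    moments: SampleMoments,
    gene: str,
    placements: Sequence[Placement],
    threshold: float,
    placement_models: Sequence[PathModel] | None = None,
    reference_model: PathModel | None = None,
) -> tuple[list[ScanRecord], ScanRecord | None, float]:
    """Fit every placement of one gene; return records, best record, base BIC.

    ``moments`` must cover the baseline genes plus ``gene``. Ties in best
    BIC are broken by smallest model_index. Pre-built placement models may be
    supplied to amortize construction across many genes.
    """
    ref = reference_model if reference_model is not None else _isolated_gene_model(model, gene)
    base_bic = fit_model(ref, moments).stats.bic
    records: list[ScanRecord] = []
    best: ScanRecord | None = None
    for k, placement in enumerate(placements):
        cand = (placement_models[k] if placement_models is not None
                else apply_placement(model, gene, placement))
        try:
            fit = fit_model(cand, moments)
        except Exception as exc:
            records.append(
                ScanRecord((gene, placement), float("nan"), float("nan"), False,
                           False, skipped_reason=str(exc),
                           model_index=placement.model_index)
            )
            continue
        delta = base_bic - fit.stats.bic
        rec = ScanRecord((gene, placement), fit.stats.bic, delta, fit.converged,
                         fit.converged and delta > threshold,
                         model_index=placement.model_index)
        records.append(rec)
        if rec.converged and (best is None or rec.bic < best.bic - 1e-12):
            best = rec
    return records, best, base_bic


def scan_candidate_genes(
    model: PathModel,
    data: pd.DataFrame,
    candidates: pd.DataFrame | Iterable[str],
    threshold: float,
) -> GeneScanResult:
    """Scan candidate genes one at a time over every placement.

    ``data`` is a samples x genes expression frame containing the baseline
    genes (and possibly more); ``candidates`` is either a frame of candidate
    columns on the same samples or a list of column names within ``data``.
    A gene is accepted when its best placement's delta BIC (versus the
    baseline augmented with the gene as an isolated variable) exceeds the
    threshold.
    """
    if isinstance(candidates, pd.DataFrame):
        cand_names = [str(c) for c in candidates.columns]
        full = pd.concat([data, candidates], axis=1)
    else:
        cand_names = [str(c) for c in candidates]
        full = data
    overlap = set(cand_names) & set(model.genes)
    if overlap:
        raise ValueError(f"candidate genes overlap the model: {sorted(overlap)}")

    placements = enumerate_gene_placements(model)
    # placement model structure is gene-name independent; build once
    placeholder = "__candidate__"
    prebuilt = [apply_placement(model, placeholder, pl) for pl in placements]
    ref_model = _isolated_gene_model(model, placeholder)

    x = full.loc[:, list(model.genes) + cand_names].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("expression data contain missing values")
    big_s = np.cov(x, rowvar=False, ddof=1)
    big_means = x.mean(axis=0)
    n = x.shape[0]
    g = len(model.genes)

    rows = []
    all_records: dict[str, list[ScanRecord]] = {}
    n_models = 0
    for j, gene in enumerate(cand_names):
        idx = list(range(g)) + [g + j]
        moments = SampleMoments(
            S=big_s[np.ix_(idx, idx)],
            means=big_means[idx],
            n=n,
            labels=tuple(model.genes) + (placeholder,),
        )
        records, best, base_bic = fit_gene_over_placements(
            model, moments, placeholder, placements, threshold,
            placement_models=prebuilt, reference_model=ref_model,
        )
        records = [replace(r, candidate=(gene, r.candidate[1])) for r in records]
        all_records[gene] = records
        n_models += len(placements)
        n_failed = sum(r.skipped_reason is not None for r in records)
        if best is None:
            rows.append({"gene": gene, "best_kind": None, "best_anchor": None,
                         "best_model_index": None, "best_bic": float("nan"),
                         "delta_bic": float("nan"), "accepted": False,
                         "n_failed": n_failed})
            continue
        pl = best.candidate[1]
        rows.append({
            "gene": gene, "best_kind": pl.kind, "best_anchor": pl.describe(),
            "best_model_index": pl.model_index, "best_bic": best.bic,
            "delta_bic": base_bic - best.bic,
            "accepted": (base_bic - best.bic) > threshold,
            "n_failed": n_failed,
        })
    summary = pd.DataFrame(rows).set_index("gene")
    return GeneScanResult(summary, all_records, threshold, n_models)


@dataclass(frozen=True)
class OverlapReport:
    shared: frozenset
    reciprocal_pairs: frozenset  # unordered pairs with both directions shared
    directed: frozenset          # shared edges whose reversal is not shared

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def intersect_scans(accepted_a: Iterable, accepted_b: Iterable) -> OverlapReport:
    """Overlap of two accepted sets (paths keyed (source, target), or genes).

    For path sets, reciprocal relationships (both a->b and b->a shared) are
    reported separately from directed singletons.
    """
    a, b = set(accepted_a), set(accepted_b)
    shared = a & b
    reciprocal = set()
    directed = set()
    for item in shared:
        if isinstance(item, tuple) and len(item) == 2:
            rev = (item[1], item[0])
            if rev in shared:
                reciprocal.add(frozenset(item))
            else:
                directed.add(item)
        else:
            directed.add(item)
    return OverlapReport(frozenset(shared), frozenset(reciprocal), frozenset(directed))


def scan_records_to_frame(records: Sequence[ScanRecord]) -> pd.DataFrame:
    """Flatten scan records to the TSV result layout."""
    rows = []
    for r in records:
        cand = r.candidate
        if isinstance(cand[1], Placement):
            gene, pl = cand
            rows.append({"candidate_id": gene, "kind": pl.kind,
                         "anchor": pl.describe(), "bic": r.bic,
                         "delta_bic": r.delta_bic, "converged": r.converged,
                         "accepted": r.accepted, "model_index": pl.model_index,
                         "skipped_reason": r.skipped_reason or ""})
        else:
            s, t = cand
            rows.append({"candidate_id": f"{s}->{t}", "kind": "path",
                         "anchor": f"{s}->{t}", "bic": r.bic,
                         "delta_bic": r.delta_bic, "converged": r.converged,
                         "accepted": r.accepted, "model_index": r.model_index,
                         "skipped_reason": r.skipped_reason or ""})
    return pd.DataFrame(rows)
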