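"""Flanking intergenic regions (FIRs) and two-speed genome compartments.

Each gene's 5' and 3' FIRs are the base counts between it and its nearest
neighboring gene, assigned strand-relatively (for a minus-strand gene the
left-hand gap is its 3' FIR). Genomes with a bipartite ("two-speed")
architecture show a bimodal joint FIR distribution: a gene-dense
compartment with short FIRs and a gene-sparse compartment with long FIRs,
the latter typically enriched for effectors. The classifier here
formalizes that picture: a gene is `sparse` when both FIRs are at or above
a threshold (a fixed bp value or a quantile of the pooled FIR values),
and category enrichment in the sparse compartment is tested with Fisher's
exact test, BH-corrected across categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CategoryLabel, GeneModel
from .stats import bh_correct, fisher_exact_2x2

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FIRRecord:
    gene_id: str
    fir5: int
    fir3: int
    boundary5: bool
    boundary3: bool

    @property
    def is_boundary(self) -> bool:
        return self.boundary5 or self.boundary3


@dataclass(frozen=True)
class FIRDensity:
    bin_edges: np.ndarray  # on the fir+1 scale, log10-spaced
    matrix: np.ndarray     # rows: fir5 bin, cols: fir3 bin
    n_genes: int


@dataclass(frozen=True)
class CompartmentCall:
    gene_id: str
    compartment: str  # "dense" | "sparse"
    threshold_bp: float


def compute_firs(genes: Sequence[GeneModel],
                 scaffold_lengths: Mapping[str, int]) -> list[FIRRecord]:
    """Per-gene 5'/3' flanking intergenic distances.

    Gaps are measured between start-sorted consecutive genes on each
    scaffold, clipped at 0 for overlapping or nested spans, and assigned to
    the 5'/3' slots according to each gene's own strand. A terminal gene's
    geneless side gets the distance to the scaffold end with the boundary
    flag set.
    """
    records: list[FIRRecord] = []
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.scaffold_id not in scaffold_lengths:
            raise ValueError(f"gene {g.gene_id}: unknown scaffold {g.scaffold_id!r}")
        if g.end > scaffold_lengths[g.scaffold_id]:
            raise ValueError(
                f"gene {g.gene_id} extends past scaffold "
                f"{g.scaffold_id} length {scaffold_lengths[g.scaffold_id]}"
            )
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    for scaffold, scaffold_genes in by_scaffold.items():
        if any(scaffold_genes[i].start > scaffold_genes[i + 1].start
               for i in range(len(scaffold_genes) - 1)):
            logger.warning("genes on %s not sorted by start; sorting", scaffold)
        ordered = sorted(scaffold_genes, key=lambda g: (g.start, g.end))
        length = scaffold_lengths[scaffold]
        for i, g in enumerate(ordered):
            if i == 0:
                left, left_boundary = g.start, True
            else:
                left, left_boundary = max(0, g.start - ordered[i - 1].end), False
            if i == len(ordered) - 1:
                right, right_boundary = length - g.end, True
            else:
                right, right_boundary = max(0, ordered[i + 1].start - g.end), False
            if g.strand == "+":
                rec = FIRRecord(g.gene_id, left, right, left_boundary, right_boundary)
            else:
                rec = FIRRecord(g.gene_id, right, left, right_boundary, left_boundary)
            records.append(rec)
    return records


def bin_fir_density(firs: Sequence[FIRRecord], n_bins: int = 30,
                    fir_range: tuple[float, float] = (1.0, 100000.0)) -> FIRDensity:
    """Joint (fir5, fir3) histogram on log10-spaced bins.

    A +1 pseudo-count puts 0-bp FIRs into the first bin; values outside the
    range clamp to the terminal bins, so every non-boundary gene is counted
    exactly once.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    usable = [f for f in firs if not f.is_boundary]
    edges = np.logspace(np.log10(fir_range[0]), np.log10(fir_range[1]), n_bins + 1)
    matrix = np.zeros((n_bins, n_bins), dtype=int)
    lo, hi = fir_range
    for f in usable:
        x = min(max(f.fir5 + 1.0, lo), hi)
        y = min(max(f.fir3 + 1.0, lo), hi)
        i = min(np.searchsorted(edges, x, side="right") - 1, n_bins - 1)
        j = min(np.searchsorted(edges, y, side="right") - 1, n_bins - 1)
        matrix[i, j] += 1
    return FIRDensity(bin_edges=edges, matrix=matrix, n_genes=len(usable))


def _resolve_threshold(firs: Sequence[FIRRecord], threshold: str | float) -> float:
    if isinstance(threshold, str):
        if not threshold.startswith("q"):
            raise ValueError(f"threshold must be a number or 'qNN', got {threshold!r}")
        q = float(threshold[1:]) / 100.0
        pooled = [f.fir5 for f in firs] + [f.fir3 for f in firs]
        return float(np.quantile(pooled, q))
    return float(threshold)


def classify_compartments(firs: Sequence[FIRRecord],
                          threshold: str | float = "q75") -> list[CompartmentCall]:
    """Label each non-boundary gene dense or sparse.

    `sparse` requires both FIRs at or above the threshold; a quantile token
    ("q75") is evaluated on the pooled non-boundary FIR values.
    """
    usable = [f for f in firs if not f.is_boundary]
    if not usable:
        raise ValueError("no non-boundary genes to classify")
    t = _resolve_threshold(usable, threshold)
    calls = []
    for f in usable:
        compartment = "sparse" if (f.fir5 >= t and f.fir3 >= t) else "dense"
        calls.append(CompartmentCall(f.gene_id, compartment, t))
    return calls


def category_fir_summary(firs: Sequence[FIRRecord],
                         labels: Iterable[CategoryLabel]) -> pd.DataFrame:
    """Mean/median FIRs per gene category (unlabeled genes are core).

    Boundary genes are excluded. A gene labelled both effector and cazyme
    is summarized as effector (the rarer class).
    """
    label_map: dict[str, str] = {}
    for lab in labels:
        prev = label_map.get(lab.gene_id)
        if prev is None or (lab.category == "effector" and prev == "cazyme"):
            label_map[lab.gene_id] = lab.category
    usable = [f for f in firs if not f.is_boundary]
    rows = []
    for category in ("core", "effector", "cazyme"):
        members = [f for f in usable
                   if label_map.get(f.gene_id, "core") == category]
        if members:
            fir5 = np.array([f.fir5 for f in members], dtype=float)
            fir3 = np.array([f.fir3 for f in members], dtype=float)
            rows.append({
                "category": category, "n": len(members),
                "mean_fir5": fir5.mean(), "mean_fir3": fir3.mean(),
                "median_fir5": float(np.median(fir5)),
                "median_fir3": float(np.median(fir3)),
            })
        else:
            rows.append({"category": category, "n": 0,
                         "mean_fir5": np.nan, "mean_fir3": np.nan,
                         "median_fir5": np.nan, "median_fir3": np.nan})
    return pd.DataFrame(rows)


def compartment_enrichment(calls: Sequence[CompartmentCall],
                           labels: Iterable[CategoryLabel],
                           categories: Sequence[str] = ("effector", "cazyme"),
                           ) -> pd.DataFrame:
    """Fisher's exact test for category enrichment in the sparse compartment.

    For each category, builds the 2x2 table
    [[category & sparse, category & dense], [other & sparse, other & dense]],
    computes the two-sided exact p and the (Haldane-corrected if needed)
    odds ratio, and BH-corrects p across the tested categories.
    """
    sparse_ids = {c.gene_id for c in calls if c.compartment == "sparse"}
    all_ids = {c.gene_id for c in calls}
    if not sparse_ids or sparse_ids == all_ids:
        raise ValueError("compartment margin is degenerate (all dense or all sparse)")
    label_map: dict[str, set[str]] = {}
    for lab in labels:
        if lab.gene_id in all_ids:
            label_map.setdefault(lab.gene_id, set()).add(lab.category)
    rows = []
    for category in categories:
        members = {g for g, cats in label_map.items() if category in cats}
        a = len(members & sparse_ids)
        b = len(members - sparse_ids)
        c = len(sparse_ids - members)
        d = len(all_ids - members - sparse_ids)
        result = fisher_exact_2x2(a, b, c, d)
        rows.append({"category": category, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": result["odds_ratio"],
                     "p_value": result["p_two_sided"]})
    df = pd.DataFrame(rows)
    df["q_value"] = bh_correct(df["p_value"].to_numpy())
    return df
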