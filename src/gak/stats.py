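"""Small statistical and normalization computations used across the pipeline.

Fisher's exact test is computed from first principles with exact integer
hypergeometric weights (the two-sided p sums the probabilities of all
tables with the observed margins that are no more probable than the
observed one); BH correction delegates to statsmodels. The remaining
operations are the printed-table normalizations: counts per 10,000 genes,
coding fraction of a genome, enzyme activity units, and ortholog-cluster
table totals.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from math import comb
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests


def round2(value: float) -> float:
    """Round half-up to 2 decimals (table formatting convention)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> dict[str, float]:
    """Two-sided Fisher's exact test for a 2x2 table [[a, b], [c, d]].

    p sums hypergeometric probabilities of every table with the same
    margins whose probability does not exceed the observed table's
    (exact integer comparison, so ties are handled without tolerance).
    The odds ratio is (a*d)/(b*c), with a 0.5 Haldane correction applied
    to every cell iff any cell is zero.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells) or not all(isinstance(x, (int, np.integer)) for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    r1, r2, c1 = a + b, c + d, a + c
    k_min, k_max = max(0, c1 - r2), min(r1, c1)
    observed_weight = comb(r1, a) * comb(r2, c)
    numerator = 0
    for k in range(k_min, k_max + 1):
        weight = comb(r1, k) * comb(r2, c1 - k)
        if weight <= observed_weight:
            numerator += weight
    p = numerator / comb(n, c1)
    if 0 in cells:
        ah, bh, ch, dh = (x + 0.5 for x in cells)
    else:
        ah, bh, ch, dh = cells
    odds_ratio = (ah * dh) / (bh * ch)
    return {"p_two_sided": min(p, 1.0), "odds_ratio": odds_ratio}


def bh_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def normalize_per_10k(count: float, total_genes: int) -> float:
    """Scale a gene-class count to a per-10,000-genes basis."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    return count / total_genes * 10000.0


def coding_fraction(total_gene_length_bp: int, genome_length_bp: int) -> float:
    """Percent of the genome covered by annotated genes, to 2 decimals."""
    if total_gene_length_bp <= 0 or genome_length_bp <= 0:
        raise ValueError("lengths must be positive")
    if total_gene_length_bp > genome_length_bp:
        raise ValueError("gene length exceeds genome length")
    return round2(total_gene_length_bp / genome_length_bp * 100.0)


def enzyme_activity(umol_glucose: float, time_min: float, volume_ml: float) -> float:
    """Enzyme activity in U/ml: 1 U releases 1 umol of product per minute."""
    if time_min <= 0 or volume_ml <= 0:
        raise ValueError("time and volume must be positive")
    return umol_glucose / (time_min * volume_ml)


def cluster_table_checks(rows: Sequence[tuple[int, int, int]]) -> dict[str, float]:
    """Column totals and singleton percentage of an ortholog-cluster table.

    Each row is (n_proteins, n_clusters, n_singletons); the singleton
    percentage is total singleton clusters over total proteins, to 2
    decimals.
    """
    if not rows:
        raise ValueError("need at least one row")
    for row in rows:
        if any(x < 0 for x in row):
            raise ValueError(f"negative entry in row {row}")
        if row[2] > row[0]:
            raise ValueError(f"singletons exceed proteins in row {row}")
    total_proteins = sum(r[0] for r in rows)
    total_singletons = sum(r[2] for r in rows)
    return {
        "total_proteins": total_proteins,
        "total_singleton_clusters": total_singletons,
        "singleton_percent": round2(total_singletons / total_proteins * 100.0),
    }
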