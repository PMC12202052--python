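"""Composition of the per-module analyses into one per-genome report.

`analyze_genome` is the in-memory composition (everything the per-module
functions compute, collected into one tidy row); `run_all` is the file
-level wrapper that reads the inputs, writes every per-module table plus
the combined row, and drops a run manifest with input digests so a report
directory is self-describing.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .fir import (bin_fir_density, category_fir_summary, classify_compartments,
                  compartment_enrichment, compute_firs)
from .io_formats import read_fasta, read_gff3, read_labels, write_bed
from .ssr import MotifSpectrum, motif_spectrum, scan_assembly, ssr_statistics
from .telomeres import find_telomeres, telomere_summary


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def analyze_genome(records, genes, labels, name: str = "genome",
                   min_len: int = 2, max_len: int = 10, min_repeats: int = 5,
                   telomere_unit: str = "TTAGGG", telomere_min_copies: int = 5,
                   telomere_window: int = 200, threshold: str | float = "q75",
                   n_bins: int = 30) -> dict:
    """Run every analysis stage on one genome; returns row + intermediates."""
    genome_length = sum(r.length for r in records)
    gc_total = sum(r.gc_percent * (r.length - r.sequence.count("N"))
                   for r in records)
    non_n = sum(r.length - r.sequence.count("N") for r in records)
    gc_percent = gc_total / non_n if non_n else 0.0

    loci = scan_assembly(records, min_len, max_len, min_repeats)
    stats = ssr_statistics(loci, genome_length, gc_percent)
    spectra = motif_spectrum(loci, genome_length, k_values=(2, 3, 4),
                             full_universe=True)

    calls = [find_telomeres(r, telomere_unit, telomere_min_copies,
                            telomere_window) for r in records]
    tel_summary = telomere_summary(calls)

    scaffold_lengths = {r.scaffold_id: r.length for r in records}
    firs = compute_firs(genes, scaffold_lengths)
    density = bin_fir_density(firs, n_bins=n_bins)
    compartments = classify_compartments(firs, threshold=threshold)
    cat_summary = category_fir_summary(firs, labels)
    enrichment = compartment_enrichment(compartments, labels)

    n_sparse = sum(1 for c in compartments if c.compartment == "sparse")
    coding_bp = sum(g.length for g in genes)
    eff = enrichment.set_index("category")
    row = {
        "genome": name,
        "length_bp": genome_length,
        "gc_percent": round(gc_percent, 2),
        "n_genes": len(genes),
        "coding_percent": round(coding_bp / genome_length * 100.0, 2),
        "ssr_count": stats.total_count,
        "ssr_bases": stats.bases_covered,
        "ssr_density_per_mb": round(stats.density_per_mb, 2),
        "ssr_coverage_percent": round(stats.coverage_percent, 4),
        "ssr_frequency_per_mb": round(stats.frequency_per_mb, 2),
        "telomere_complete": tel_summary["complete"],
        "telomere_one_end": tel_summary["one_end"],
        "telomere_none": tel_summary["none"],
        "sparse_gene_percent": round(n_sparse / len(compartments) * 100.0, 2),
        "effector_or": round(float(eff.loc["effector", "odds_ratio"]), 4),
        "effector_q": float(eff.loc["effector", "q_value"]),
        "cazyme_or": round(float(eff.loc["cazyme", "odds_ratio"]), 4),
        "cazyme_q": float(eff.loc["cazyme", "q_value"]),
    }
    return {
        "row": row, "loci": loci, "stats": stats, "spectra": spectra,
        "telomere_calls": calls, "firs": firs, "density": density,
        "compartments": compartments, "category_summary": cat_summary,
        "enrichment": enrichment,
    }


def _spectrum_frame(spectra: Sequence[MotifSpectrum], genome: str) -> pd.DataFrame:
    rows = []
    for spec in spectra:
        for motif, (count, per_mb) in spec.rows.items():
            rows.append({"genome": genome, "k": spec.k, "motif": motif,
                         "count": count, "per_mb": round(per_mb, 4)})
    return pd.DataFrame(rows)


def run_all(fasta: str | Path, gff3: str | Path, labels_path: str | Path | None,
            out_dir: str | Path, name: str | None = None, **params) -> pd.DataFrame:
    """Full pipeline on one genome from files; writes a report directory."""
    fasta, gff3 = Path(fasta), Path(gff3)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = name or fasta.stem
    records = read_fasta(fasta)
    genes = read_gff3(gff3)
    gene_ids = {g.gene_id for g in genes}
    scaffolds = {r.scaffold_id for r in records}
    missing = {g.scaffold_id for g in genes} - scaffolds
    if missing:
        raise ValueError(f"gene scaffolds absent from FASTA: {sorted(missing)}")
    labels = read_labels(labels_path, gene_ids) if labels_path else []

    result = analyze_genome(records, genes, labels, name=name, **params)

    write_bed(result["loci"], out_dir / "ssrs.bed",
              {r.scaffold_id: r.length for r in records})
    _spectrum_frame(result["spectra"], name).to_csv(
        out_dir / "spectrum.tsv", sep="\t", index=False)
    pd.DataFrame([{"scaffold": c.scaffold_id, "end5": c.end5, "copies5": c.copies5,
                   "end3": c.end3, "copies3": c.copies3,
                   "class": ("complete", "one_end", "none")[2 - c.n_ends]}
                  for c in result["telomere_calls"]]).to_csv(
        out_dir / "telomeres.tsv", sep="\t", index=False)
    comp_map = {c.gene_id: c.compartment for c in result["compartments"]}
    pd.DataFrame([{**asdict(f), "compartment": comp_map.get(f.gene_id, "")}
                  for f in result["firs"]]).to_csv(
        out_dir / "firs.tsv", sep="\t", index=False)
    density = result["density"]
    pd.DataFrame(density.matrix,
                 index=[f"{e:.1f}" for e in density.bin_edges[:-1]],
                 columns=[f"{e:.1f}" for e in density.bin_edges[:-1]]).to_csv(
        out_dir / "density.tsv", sep="\t")
    result["category_summary"].to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    result["enrichment"].to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    report = pd.DataFrame([result["row"]])
    report.to_csv(out_dir / "report.tsv", sep="\t", index=False)

    manifest = {
        "command": " ".join(sys.argv) if sys.argv else "run_all",
        "parameters": {k: str(v) for k, v in params.items()},
        "inputs": {str(fasta): _sha256(fasta), str(gff3): _sha256(gff3),
                   **({str(labels_path): _sha256(labels_path)} if labels_path else {})},
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out_dir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=1, sort_keys=True)
        out.write("\n")
    return report


def compare_genomes(results: Sequence[dict]) -> dict[str, pd.DataFrame]:
    """Stack per-genome results into cross-genome matrices.

    Returns a per-genome statistics table and, per motif length k, a
    matrix of per-Mb motif densities (rows: canonical motifs, union across
    genomes with zeros filled; columns: genomes in input order).
    """
    if not results:
        raise ValueError("need at least one analyzed genome")
    stats_table = pd.DataFrame([r["row"] for r in results])
    k_sets = [tuple(spec.k for spec in r["spectra"]) for r in results]
    if len(set(k_sets)) > 1:
        raise ValueError(f"inconsistent motif-length ranges across genomes: {k_sets}")
    matrices: dict[str, pd.DataFrame] = {"stats": stats_table}
    for ki, k in enumerate(k_sets[0]):
        columns = {}
        for r in results:
            per_mb = {motif: per_mb for motif, (_, per_mb) in r["spectra"][ki].rows.items()}
            columns[r["row"]["genome"]] = per_mb
        matrix = pd.DataFrame(columns).fillna(0.0).sort_index()
        matrices[f"k{k}"] = matrix
    return matrices
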