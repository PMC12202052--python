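"""Synthetic assembly generator with planted ground truth.

Emulates the genome-architecture features the analyses measure, on a
scaled-down assembly that is fast to scan:

* scaffolds laid out as alternating gene-dense and gene-sparse blocks,
  with inter-gene gaps drawn from short vs long log-normal distributions
  (a bipartite, "two-speed" architecture);
* effector/CAZyme labels assigned per gene with compartment-conditional
  probabilities, so effectors preferentially occupy the sparse compartment;
* perfect tandem repeats planted into intergenic gaps with guard bases, so
  their exact spans are recoverable;
* telomeric repeat arrays written at configured scaffold termini.

Everything is drawn from one seeded generator, so a config (including its
seed) maps to byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from math import log
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (CategoryLabel, GeneModel, GenomeRecord, write_fasta,
                         write_gff3, write_labels)
from .ssr import SSRLocus, canonical_motif, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic assembly.

    Gap distributions are log-normal on the natural-log scale; the default
    dense/sparse parameters (ln 200 / ln 5000, sd 0.5) give ~200 bp gaps in
    the dense compartment and ~5 kb gaps in the sparse one. Sparse blocks
    hold fewer genes than dense blocks because gene-sparse regions are, by
    definition, gene-poor.
    """

    seed: int = 0
    n_scaffolds: int = 5
    genes_per_scaffold: int = 100
    gc_target: float = 0.52
    gene_length_mean: float = 1500.0
    gene_length_sd: float = 300.0
    gene_length_min: int = 300
    dense_gap_log_mean: float = log(200.0)
    dense_gap_log_sd: float = 0.5
    sparse_gap_log_mean: float = log(5000.0)
    sparse_gap_log_sd: float = 0.5
    dense_block_genes: int = 40
    sparse_block_genes: int = 10
    p_effector_sparse: float = 0.75
    p_effector_dense: float = 0.05
    p_cazyme_sparse: float = 0.10
    p_cazyme_dense: float = 0.10
    planted_ssrs: tuple[tuple[str, int, int], ...] = (
        ("AT", 8, 10), ("AAG", 6, 6), ("ACGT", 5, 4))  # (motif, units, count)
    telomere_unit: str = "TTAGGG"
    telomere_copies: int = 10
    telomere_plan: tuple[tuple[bool, bool], ...] | None = None  # per scaffold (end5, end3)
    tail_pad_bp: int = 600

    def resolved_telomere_plan(self) -> list[tuple[bool, bool]]:
        """Default: first scaffold complete, middle ones 3'-only, last bare."""
        if self.telomere_plan is not None:
            if len(self.telomere_plan) != self.n_scaffolds:
                raise ValueError("telomere_plan length must equal n_scaffolds")
            return list(self.telomere_plan)
        plan = []
        for i in range(self.n_scaffolds):
            if i == 0:
                plan.append((True, True))
            elif i == self.n_scaffolds - 1:
                plan.append((False, False))
            else:
                plan.append((False, True))
        return plan


@dataclass
class SimulatedAssembly:
    records: list[GenomeRecord]
    genes: list[GeneModel]
    labels: list[CategoryLabel]
    truth: dict = field(default_factory=dict)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _block_types(config: SimulationConfig) -> list[str]:
    """Compartment of each gene index on a scaffold (alternating blocks)."""
    types: list[str] = []
    dense = True
    while len(types) < config.genes_per_scaffold:
        size = config.dense_block_genes if dense else config.sparse_block_genes
        types.extend(["dense" if dense else "sparse"] * size)
        dense = not dense
    return types[: config.genes_per_scaffold]


def simulate_assembly(config: SimulationConfig) -> SimulatedAssembly:
    """Generate one assembly (in memory) with full ground truth."""
    rng = np.random.default_rng(config.seed)
    telomere_len = len(config.telomere_unit) * config.telomere_copies
    plan = config.resolved_telomere_plan()

    records: list[GenomeRecord] = []
    genes: list[GeneModel] = []
    labels: list[CategoryLabel] = []
    truth_genes = []
    truth_telomeres = []
    gaps_catalog: list[tuple[int, int, int]] = []  # (scaffold idx, gap start, gap end)

    for si in range(config.n_scaffolds):
        scaffold = f"scf{si + 1}"
        end5, end3 = plan[si]
        pos = 0
        gene_spans: list[tuple[int, int, str, str]] = []  # start, end, strand, compartment
        prev_end = 0
        for gi, compartment in enumerate(_block_types(config)):
            if compartment == "dense":
                gap = rng.lognormal(config.dense_gap_log_mean, config.dense_gap_log_sd)
            else:
                gap = rng.lognormal(config.sparse_gap_log_mean, config.sparse_gap_log_sd)
            gap = max(1, int(round(gap)))
            if gi == 0 and end5:
                gap = max(gap, telomere_len + 20)  # keep gene 1 clear of the telomere
            length = max(config.gene_length_min,
                         int(round(rng.normal(config.gene_length_mean,
                                              config.gene_length_sd))))
            start = pos + gap
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            gene_spans.append((start, end, strand, compartment))
            if gi > 0:
                gaps_catalog.append((si, prev_end, start))
            prev_end = end
            pos = end
        scaffold_len = pos + max(config.tail_pad_bp, telomere_len + 20)
        seq = _random_bases(rng, scaffold_len, config.gc_target)

        for gi, (start, end, strand, compartment) in enumerate(gene_spans):
            gene_id = f"{scaffold}_g{gi + 1:04d}"
            genes.append(GeneModel(gene_id, scaffold, start, end, strand))
            p_eff = (config.p_effector_sparse if compartment == "sparse"
                     else config.p_effector_dense)
            p_caz = (config.p_cazyme_sparse if compartment == "sparse"
                     else config.p_cazyme_dense)
            category = "core"
            if rng.random() < p_eff:
                category = "effector"
            elif rng.random() < p_caz:
                category = "cazyme"
            if category != "core":
                labels.append(CategoryLabel(gene_id, category))
            truth_genes.append({"gene_id": gene_id, "scaffold": scaffold,
                                "start": start, "end": end, "strand": strand,
                                "compartment": compartment, "category": category})

        if end5:
            unit5 = reverse_complement(config.telomere_unit)
            tel = (unit5 * config.telomere_copies).encode()
            seq[: len(tel)] = np.frombuffer(tel, dtype=np.uint8)
        if end3:
            tel = (config.telomere_unit * config.telomere_copies).encode()
            seq[-len(tel):] = np.frombuffer(tel, dtype=np.uint8)
        truth_telomeres.append({"scaffold": scaffold, "end5": end5, "end3": end3,
                                "copies": config.telomere_copies if (end5 or end3) else 0})
        records.append(GenomeRecord(scaffold, seq.tobytes().decode()))

    truth_ssrs = _plant_ssrs(config, rng, records, gaps_catalog)

    truth = {
        "config": {k: v for k, v in asdict(config).items()},
        "genes": truth_genes,
        "ssrs": truth_ssrs,
        "telomeres": truth_telomeres,
    }
    return SimulatedAssembly(records=records, genes=genes, labels=labels, truth=truth)


def _plant_ssrs(config: SimulationConfig, rng: np.random.Generator,
                records: list[GenomeRecord],
                gaps_catalog: list[tuple[int, int, int]]) -> list[dict]:
    """Overwrite intergenic stretches with perfect tandem arrays.

    One array per chosen gap, framed by guard bases that block single-base
    extension, so a scanner should recover the planted span exactly.
    """
    requests: list[tuple[str, int]] = []
    for motif, units, count in config.planted_ssrs:
        canonical_motif(motif)  # validates the motif alphabet
        requests.extend([(motif, units)] * count)
    # need gap room: 1 guard + array + 1 guard, away from gap edges by 2 bp
    usable = []
    for si, gs, ge in gaps_catalog:
        usable.append((si, gs + 2, ge - 2))
    order = rng.permutation(len(requests))
    arrays = [bytearray(rec.sequence.encode()) for rec in records]
    chosen: list[tuple[int, int, int]] = []  # (scaffold idx, start, end) incl. guards
    truth: list[dict] = []
    for idx in order:
        motif, units = requests[idx]
        span = len(motif) * units
        need = span + 2
        candidates = [i for i, (si, lo, hi) in enumerate(usable) if hi - lo >= need]
        if not candidates:
            raise ValueError("infeasible config: planted SSRs exceed intergenic space")
        gap_i = candidates[rng.integers(len(candidates))]
        si, lo, hi = usable.pop(gap_i)
        start = int(lo + rng.integers(hi - lo - need + 1)) + 1  # +1 for left guard
        array = (motif * units).encode()
        arrays[si][start : start + span] = array
        left_guard = rng.choice([b for b in "ACGT" if b != motif[-1]])
        right_guard = rng.choice([b for b in "ACGT" if b != motif[0]])
        arrays[si][start - 1] = ord(left_guard)
        arrays[si][start + span] = ord(right_guard)
        chosen.append((si, start - 1, start + span + 1))
        truth.append({"scaffold": records[si].scaffold_id, "start": start,
                      "end": start + span, "period": len(motif), "motif": motif,
                      "canonical": canonical_motif(motif), "units": units})
    for i, rec in enumerate(records):
        records[i] = GenomeRecord(rec.scaffold_id, arrays[i].decode())
    truth.sort(key=lambda t: (t["scaffold"], t["start"]))
    return truth


def write_assembly(sim: SimulatedAssembly, out_dir: str | Path,
                   prefix: str = "synthetic") -> dict[str, Path]:
    """Write FASTA, GFF3, labels TSV and ground-truth JSON; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / f"{prefix}.fasta",
        "gff3": out_dir / f"{prefix}.gff3",
        "labels": out_dir / f"{prefix}.labels.tsv",
        "truth": out_dir / f"{prefix}.truth.json",
    }
    write_fasta(sim.records, paths["fasta"])
    write_gff3(sim.genes, paths["gff3"])
    write_labels(sim.labels, paths["labels"])
    with open(paths["truth"], "w") as out:
        json.dump(sim.truth, out, indent=1, sort_keys=True)
        out.write("\n")
    return paths


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def truth_compare_ssrs(truth_ssrs: Sequence[dict],
                       observed: Sequence[SSRLocus]) -> dict[str, float]:
    """Recall/precision of observed SSR loci against the planted truth.

    A planted locus is recovered iff an observed locus matches scaffold,
    exact span, and canonical motif. Precision counts non-planted
    (background) discoveries against the observed total.
    """
    truth_keys = {(t["scaffold"], t["start"], t["end"], t["canonical"])
                  for t in truth_ssrs}
    obs_scaffolds = {L.scaffold_id for L in observed}
    truth_scaffolds = {t["scaffold"] for t in truth_ssrs}
    if truth_scaffolds and obs_scaffolds and not (obs_scaffolds & truth_scaffolds):
        raise ValueError("observed and truth scaffold namespaces are disjoint")
    obs_keys = {(L.scaffold_id, L.start, L.end, L.canonical) for L in observed}
    hits = truth_keys & obs_keys
    recall = len(hits) / len(truth_keys) if truth_keys else 1.0
    precision = len(hits) / len(obs_keys) if obs_keys else 0.0
    return {"recall": recall, "precision": precision,
            "exact_match_fraction": recall}


def truth_compare_telomeres(truth_telomeres: Sequence[dict],
                            calls) -> dict[str, float]:
    """Recall/precision of telomere end calls against the planted plan."""
    planted = {(t["scaffold"], side)
               for t in truth_telomeres for side in ("end5", "end3") if t[side]}
    called = set()
    for call in calls:
        if call.end5:
            called.add((call.scaffold_id, "end5"))
        if call.end3:
            called.add((call.scaffold_id, "end3"))
    hits = planted & called
    recall = len(hits) / len(planted) if planted else 1.0
    precision = len(hits) / len(called) if called else (1.0 if not planted else 0.0)
    return {"recall": recall, "precision": precision,
            "exact_match_fraction": recall}
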