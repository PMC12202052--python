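"""Readers and writers for the formats the pipeline touches.

All coordinates are 0-based half-open internally; conversion to and from
1-based inclusive (GFF3) happens only here, at the file boundary.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
CATEGORIES = ("effector", "cazyme", "core")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class GenomeRecord:
    """One scaffold: uppercase DNA over {A,C,G,T,N}."""

    scaffold_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        """GC percentage over non-N bases (0.0 for an all-N scaffold)."""
        seq = self.sequence
        n_valid = len(seq) - seq.count("N")
        if n_valid == 0:
            return 0.0
        gc = seq.count("G") + seq.count("C")
        return gc / n_valid * 100.0


@dataclass(frozen=True)
class GeneModel:
    """A gene span, 0-based half-open, with strand '+' or '-'."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CategoryLabel:
    gene_id: str
    category: str
    subfamily: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (optionally gzipped) FASTA file into GenomeRecords.

    Sequences are uppercased; characters outside {A,C,G,T,N} are mapped to
    N and counted in a logged warning. Duplicate headers and empty files
    raise :class:`FormatError`.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    n_mapped = 0
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate FASTA header: {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            bad = [ch for ch in set(seq) if ch not in VALID_BASES]
            if bad:
                for ch in bad:
                    n_mapped += seq.count(ch)
                    seq = seq.replace(ch, "N")
            records.append(GenomeRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if n_mapped:
        logger.warning("%d non-ACGTN characters mapped to N in %s", n_mapped, path)
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.scaffold_id}\n")
            for i in range(0, rec.length, width):
                out.write(rec.sequence[i : i + width] + "\n")


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in field.rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Read gene models of one feature type from a GFF3 file.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; the gene id is taken from the ID
    attribute. Rows with end < start or missing ID raise FormatError with
    the offending line number.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 GFF3 columns, got {len(fields)}")
            if fields[2] != feature_type:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(f"line {lineno}: end {end1} < start {start1}")
            attrs = _parse_gff3_attributes(fields[8])
            if "ID" not in attrs or not attrs["ID"]:
                raise FormatError(f"line {lineno}: missing ID attribute")
            gene_id = attrs["ID"]
            if gene_id in seen:
                raise FormatError(f"line {lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            strand = fields[6] if fields[6] in ("+", "-") else "+"
            genes.append(GeneModel(gene_id, fields[0], start1 - 1, end1, strand))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path, feature_type: str = "gene",
               source: str = "gak") -> None:
    """Write gene models as GFF3 (coordinates back to 1-based inclusive)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            out.write(
                f"{g.scaffold_id}\t{source}\t{feature_type}\t{g.start + 1}\t{g.end}"
                f"\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_labels(path: str | Path, known_gene_ids: set[str] | None = None) -> list[CategoryLabel]:
    """Read gene-category labels from a TSV (gene_id, category[, subfamily]).

    Unknown category strings raise; labels for genes absent from
    `known_gene_ids` (when given) are dropped with a warning.
    """
    labels: list[CategoryLabel] = []
    n_dropped = 0
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue  # header row
            gene_id, category = fields[0], fields[1]
            subfamily = fields[2] if len(fields) > 2 and fields[2] else None
            if category not in CATEGORIES:
                raise ValueError(
                    f"line {lineno}: unknown category {category!r}; expected one of {CATEGORIES}"
                )
            if known_gene_ids is not None and gene_id not in known_gene_ids:
                n_dropped += 1
                continue
            labels.append(CategoryLabel(gene_id, category, subfamily))
    if n_dropped:
        logger.warning("%d label rows referenced unknown genes and were dropped", n_dropped)
    return labels


def write_labels(labels: Iterable[CategoryLabel], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("gene_id\tcategory\tsubfamily\n")
        for lab in labels:
            out.write(f"{lab.gene_id}\t{lab.category}\t{lab.subfamily or ''}\n")


def write_bed(records: Sequence, path: str | Path,
              scaffold_lengths: dict[str, int] | None = None) -> None:
    """Write SSR loci (or any records with scaffold_id/start/end) as BED6.

    Name is the motif (or a `name` attribute), score the unit count (or 0),
    strand '+'. Output is sorted by (scaffold, start); spans beyond a known
    scaffold length raise ValueError.
    """
    rows = []
    for rec in records:
        scaffold = rec.scaffold_id
        start, end = rec.start, rec.end
        if scaffold_lengths is not None:
            limit = scaffold_lengths.get(scaffold)
            if limit is not None and end > limit:
                raise ValueError(
                    f"span [{start},{end}) beyond scaffold {scaffold} length {limit}"
                )
        name = getattr(rec, "motif", None) or getattr(rec, "name", ".")
        score = getattr(rec, "units", 0)
        rows.append((scaffold, start, end, name, score))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as out:
        for scaffold, start, end, name, score in rows:
            out.write(f"{scaffold}\t{start}\t{end}\t{name}\t{score}\t+\n")
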