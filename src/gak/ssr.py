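"""Perfect tandem repeat (SSR / microsatellite) detection and statistics.

An SSR locus is a maximal perfect tandem run of a short motif (default
period 2-10 bp) repeated at least `min_repeats` times. Detection is
strand-symmetric: each genomic locus is reported once, on forward-strand
coordinates, and its motif is normalized to a canonical representative of
the rotation / reverse-complement equivalence class (so e.g. TG, GT, CA
and AC all report as AC). Derived statistics follow the common per-Mb
normalizations: density (bases covered per Mb), coverage (% of the genome
covered), and frequency (loci per Mb).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GenomeRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _min_period(motif: str) -> int:
    """Smallest p such that motif is a whole number of repeats of motif[:p]."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif[:p] * (n // p) == motif:
            return p
    return n


def canonical_motif(motif: str) -> str:
    """Canonical representative: lexicographic minimum over all rotations
    of the motif and all rotations of its reverse complement."""
    if not motif or any(ch not in "ACGT" for ch in motif):
        raise ValueError(f"motif must be non-empty over ACGT, got {motif!r}")
    n = len(motif)
    doubled = motif + motif
    rc = reverse_complement(motif)
    rc_doubled = rc + rc
    candidates = [doubled[i : i + n] for i in range(n)]
    candidates += [rc_doubled[i : i + n] for i in range(n)]
    return min(candidates)


@dataclass(frozen=True)
class SSRLocus:
    """One maximal perfect tandem repeat on forward-strand coordinates.

    The span may include a trailing/leading partial unit; `units` counts
    complete units only (floor(span / period)).
    """

    scaffold_id: str
    start: int
    end: int
    period: int
    motif: str
    canonical: str
    units: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SSRStats:
    total_count: int
    bases_covered: int
    density_per_mb: float
    coverage_percent: float
    frequency_per_mb: float
    gc_percent: float


def _segments_without_n(seq: str):
    """Yield (offset, subsequence) for maximal N-free stretches."""
    start = None
    for i, ch in enumerate(seq):
        if ch == "N":
            if start is not None:
                yield start, seq[start:i]
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, seq[start:]


def _candidate_runs(seq: str, period: int, min_repeats: int):
    """Maximal tandem runs of a fixed period in an N-free sequence.

    A run is a maximal interval where seq[i] == seq[i + period]; its span
    extends `period` bases past the last matching position (covering the
    final unit and any trailing partial).
    """
    n = len(seq)
    if n < period * min_repeats:
        return
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    match = arr[:-period] == arr[period:]
    if not match.any():
        return
    # run-length segmentation of the boolean match vector
    padded = np.concatenate(([False], match, [False]))
    diffs = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diffs == 1)[0]
    ends = np.nonzero(diffs == -1)[0]
    for s, e in zip(starts, ends):
        span_end = int(e) + period
        span = span_end - int(s)
        units = span // period
        if units < min_repeats:
            continue
        yield int(s), span_end, units


def find_ssrs(record: GenomeRecord, min_len: int = 2, max_len: int = 10,
              min_repeats: int = 5) -> list[SSRLocus]:
    """Find all maximal perfect tandem repeats with period in
    [min_len, max_len] repeated at least `min_repeats` times.

    Candidate runs whose motif is itself periodic (e.g. "ATAT" at period 4)
    are discarded in favor of the shorter period. Overlapping candidates of
    different periods are resolved greedily: longer span wins, ties go to
    the smaller period, then to the leftmost start. Runs containing N are
    split at the N; output is sorted by start.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError("require 1 <= min_len <= max_len")
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    candidates: list[SSRLocus] = []
    for offset, segment in _segments_without_n(record.sequence):
        for period in range(min_len, max_len + 1):
            for s, e, units in _candidate_runs(segment, period, min_repeats):
                motif = segment[s : s + period]
                if _min_period(motif) != period:
                    continue  # run is already reported at its true period
                candidates.append(
                    SSRLocus(record.scaffold_id, offset + s, offset + e,
                             period, motif, canonical_motif(motif), units)
                )
    # overlap resolution: longer span first, then smaller period, then leftmost
    candidates.sort(key=lambda L: (-L.span, L.period, L.start))
    accepted: list[SSRLocus] = []
    occupied: list[tuple[int, int]] = []
    for cand in candidates:
        if any(cand.start < e and s < cand.end for s, e in occupied):
            continue
        accepted.append(cand)
        occupied.append((cand.start, cand.end))
    accepted.sort(key=lambda L: L.start)
    return accepted


def scan_assembly(records: Iterable[GenomeRecord], min_len: int = 2,
                  max_len: int = 10, min_repeats: int = 5) -> list[SSRLocus]:
    """find_ssrs over every scaffold, sorted by (scaffold, start)."""
    loci: list[SSRLocus] = []
    for rec in records:
        loci.extend(find_ssrs(rec, min_len, max_len, min_repeats))
    loci.sort(key=lambda L: (L.scaffold_id, L.start))
    return loci


def merged_intervals(loci: Iterable[SSRLocus]) -> dict[str, list[tuple[int, int]]]:
    """Union of locus spans per scaffold; zero-gap adjacent loci merge."""
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for L in loci:
        by_scaffold.setdefault(L.scaffold_id, []).append((L.start, L.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for scaffold, spans in by_scaffold.items():
        spans.sort()
        out = [spans[0]]
        for s, e in spans[1:]:
            if s > out[-1][1]:
                out.append((s, e))
            else:
                out[-1] = (out[-1][0], max(out[-1][1], e))
        merged[scaffold] = out
    return merged


def merged_bases(loci: Iterable[SSRLocus]) -> int:
    """Total length of the union of locus spans."""
    return sum(e - s for spans in merged_intervals(loci).values()
               for s, e in spans)


def ssr_statistics(loci: Sequence[SSRLocus], genome_length: int,
                   gc_percent: float = float("nan")) -> SSRStats:
    """Per-genome SSR summary: count, covered bases, and the per-Mb and
    percent normalizations."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    bases = merged_bases(loci) if loci else 0
    mb = genome_length / 1e6
    return SSRStats(
        total_count=len(loci),
        bases_covered=bases,
        density_per_mb=bases / mb,
        coverage_percent=bases / genome_length * 100.0,
        frequency_per_mb=len(loci) / mb,
        gc_percent=gc_percent,
    )


def _canonical_universe(k: int) -> list[str]:
    """All canonical period-minimal motifs of length k (e.g. 4 dimers)."""
    from itertools import product

    reps = set()
    for combo in product("ACGT", repeat=k):
        motif = "".join(combo)
        if _min_period(motif) != k:
            continue
        reps.add(canonical_motif(motif))
    return sorted(reps)


@dataclass(frozen=True)
class MotifSpectrum:
    k: int
    rows: Mapping[str, tuple[int, float]]  # canonical motif -> (count, per_mb)

    @property
    def total_count(self) -> int:
        return sum(count for count, _ in self.rows.values())


def motif_spectrum(loci: Sequence[SSRLocus], genome_length: int,
                   k_values: Sequence[int] = (2, 3, 4),
                   full_universe: bool = False) -> list[MotifSpectrum]:
    """Per-period canonical-motif counts with per-Mb normalization.

    With `full_universe`, motifs absent from the genome appear with count 0
    (one row per canonical period-minimal motif of length k), which is what
    a cross-genome heatmap needs to show absences.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if any(k < 1 for k in k_values):
        raise ValueError("k values must be positive")
    mb = genome_length / 1e6
    spectra = []
    for k in k_values:
        counts: dict[str, int] = {}
        if full_universe:
            counts = {m: 0 for m in _canonical_universe(k)}
        for L in loci:
            if L.period == k:
                counts[L.canonical] = counts.get(L.canonical, 0) + 1
        rows = {m: (c, c / mb) for m, c in sorted(counts.items())}
        spectra.append(MotifSpectrum(k=k, rows=rows))
    return spectra


def assembly_ssr_report(records: Iterable[GenomeRecord], min_len: int = 2,
                        max_len: int = 10, min_repeats: int = 5) -> dict[str, float]:
    """Scan a whole assembly and report both raw and merged SSR counts.

    The raw count treats zero-gap adjacent loci of different motifs
    (compound SSRs) as separate loci; the merged count collapses them into
    union intervals. Detection tools differ in this convention, so both
    are reported for comparisons against external counts.
    """
    records = list(records)
    loci = scan_assembly(records, min_len, max_len, min_repeats)
    genome_length = sum(r.length for r in records)
    stats = ssr_statistics(loci, genome_length)
    n_merged = sum(len(spans) for spans in merged_intervals(loci).values())
    return {
        "genome_length_bp": genome_length,
        "ssr_count_raw": stats.total_count,
        "ssr_count_merged": n_merged,
        "bases_covered": stats.bases_covered,
        "coverage_percent": stats.coverage_percent,
        "density_per_mb": stats.density_per_mb,
        "frequency_per_mb": stats.frequency_per_mb,
    }


def ssr_proportion_by_class(loci: Sequence[SSRLocus]) -> dict[int, float]:
    """Percent of loci per period class (sums to 100 over observed classes)."""
    if not loci:
        return {}
    counts: dict[int, int] = {}
    for L in loci:
        counts[L.period] = counts.get(L.period, 0) + 1
    total = len(loci)
    return {k: counts[k] / total * 100.0 for k in sorted(counts)}
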