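"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive results from first principles (regex scans,
exact rational enumeration) rather than sharing code with the package.
"""

from __future__ import annotations

import re
from fractions import Fraction
from math import comb


def oracle_min_period(motif: str) -> int:
    for p in range(1, len(motif)):
        if len(motif) % p == 0 and motif[:p] * (len(motif) // p) == motif:
            return p
    return len(motif)


def oracle_canonical(motif: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[ch] for ch in reversed(motif))
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return min(rotations)


def oracle_find_ssrs(seq: str, min_len: int = 2, max_len: int = 10,
                     min_repeats: int = 5) -> list[tuple[int, int, int, str, int]]:
    """Brute-force tandem-repeat scan via overlapping regex lookahead.

    Returns (start, end, period, canonical motif, units) after applying
    the period-minimality and overlap rules: maximal runs only, longest
    span wins, ties to smaller period, then leftmost.
    """
    runs: set[tuple[int, int, int]] = set()
    for nfree in re.finditer(r"[^N]+", seq):
        off, seg = nfree.start(), nfree.group()
        for p in range(min_len, max_len + 1):
            pattern = re.compile(r"(?=(.{%d})\1{%d,})" % (p, min_repeats - 1))
            for m in pattern.finditer(seg):
                s = m.start()
                e = s + p * min_repeats
                while e < len(seg) and seg[e] == seg[e - p]:
                    e += 1
                while s > 0 and seg[s - 1] == seg[s - 1 + p]:
                    s -= 1
                if (e - s) // p >= min_repeats:
                    runs.add((off + s, off + e, p))
    candidates = []
    for s, e, p in runs:
        motif = seq[s : s + p]
        if oracle_min_period(motif) != p:
            continue
        candidates.append((s, e, p, oracle_canonical(motif), (e - s) // p))
    candidates.sort(key=lambda r: (-(r[1] - r[0]), r[2], r[0]))
    accepted: list[tuple[int, int, int, str, int]] = []
    for cand in candidates:
        if all(cand[1] <= a[0] or a[1] <= cand[0] for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda r: r[0])
    return accepted


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p by full enumeration with rationals."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return total


def oracle_bh(p_values: list[float]) -> list[float]:
    """Step-up BH by the textbook formula."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p_values[i] * m / rank_from_top)
        q[i] = min(running_min, 1.0)
    return q
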