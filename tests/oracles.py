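"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — per-position boolean arrays,
full enumerations, textbook formulas — and shares no code with the
package's own algorithms.
"""

from __future__ import annotations

import math

import numpy as np


def coverage_by_positions(intervals, ref_length: int) -> int:
    """Covered length via a per-position boolean array."""
    mask = np.zeros(ref_length, dtype=bool)
    for lo, hi in intervals:
        mask[max(lo, 0): min(hi, ref_length)] = True
    return int(mask.sum())


def n50_by_definition(lengths) -> int:
    """Largest L such that contigs of length >= L sum to >= half the total."""
    total = sum(lengths)
    best = None
    for L in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= L) >= total / 2:
            best = L
            break
    return best


def best_hit_by_scan(rows) -> dict[str, str]:
    """Per query, the subject maximizing (bitscore, -evalue, len, smaller id)."""
    by_query: dict[str, list] = {}
    for r in rows:
        by_query.setdefault(r.qseqid, []).append(r)
    out = {}
    for q, hits in by_query.items():
        winner = hits[0]
        for r in hits[1:]:
            key_r = (r.bitscore, -r.evalue, r.aln_len, [-ord(ch) for ch in r.sseqid])
            key_w = (winner.bitscore, -winner.evalue, winner.aln_len,
                     [-ord(ch) for ch in winner.sseqid])
            if key_r > key_w:
                winner = r
        out[q] = winner.sseqid
    return out


def rbh_by_enumeration(rows_ab, rows_ba) -> set[tuple[str, str]]:
    """Mutual-argmax pairs via two independent best-hit scans."""
    fwd = best_hit_by_scan(rows_ab)
    rev = best_hit_by_scan(rows_ba)
    return {(a, b) for a, b in fwd.items() if rev.get(b) == a}


def fisher_two_sided_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Sum hypergeometric probabilities of tables no more probable than observed."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def spearman_by_ranks(xs, ys) -> float:
    """Pearson correlation of average ranks."""

    def ranks(vals):
        order = sorted(range(len(vals)), key=lambda i: vals[i])
        rk = [0.0] * len(vals)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                rk[order[k]] = avg
            i = j + 1
        return rk

    rx, ry = ranks(xs), ranks(ys)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
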