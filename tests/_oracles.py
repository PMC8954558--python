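"""Independent reference implementations used as test oracles.

Everything here is deliberately written from scratch (naive, brute-force or
closed-form), without importing the implementation paths it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# --- trimming ----------------------------------------------------------------


def reference_trim(seq, quals, leading_q=18, trailing_q=18, window=4, window_q=22, min_len=20):
    """Step-by-step re-application of the trimming rules; returns (seq, quals) or None."""
    quals = list(quals)
    while quals and quals[0] < leading_q:
        quals.pop(0)
        seq = seq[1:]
    while quals and quals[-1] < trailing_q:
        quals.pop()
        seq = seq[:-1]
    if 0 < len(quals) < window:
        if sum(quals) / len(quals) < window_q:
            seq, quals = "", []
    else:
        cut = None
        for s in range(len(quals) - window + 1):
            if sum(quals[s : s + window]) / window < window_q:
                cut = s
                break
        if cut is not None:
            while cut > 0 and quals[cut - 1] < window_q:
                cut -= 1
            seq, quals = seq[:cut], quals[:cut]
    if len(seq) < min_len:
        return None
    return seq, tuple(quals)


# --- alignment ---------------------------------------------------------------


def brute_force_align(seq: str, references: dict[str, str], max_mismatch: int):
    """Exhaustive Hamming scan over every position of every reference, both
    strands.  Returns (mismatches, target, start, strand, multiplicity) of the
    best locus under the tie-break (mm, target, start, + before -), or None."""
    length = len(seq)
    hits = []
    for strand_rank, query in enumerate((seq, revcomp(seq))):
        for name in references:
            ref = references[name]
            for start in range(len(ref) - length + 1):
                mm = sum(
                    1
                    for a, b in zip(query, ref[start : start + length])
                    if a != b or a == "N"
                )
                if mm <= max_mismatch:
                    hits.append((mm, name, start, strand_rank))
    if not hits:
        return None
    hits.sort()
    mm, name, start, strand_rank = hits[0]
    multiplicity = sum(1 for h in hits if h[0] == mm)
    return mm, name, start, "+" if strand_rank == 0 else "-", multiplicity


# --- interval algebra --------------------------------------------------------


def sweep_merge(intervals, gap=0):
    """Sweep-line interval merge of (chrom, start, end) triples."""
    out = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s - cur_e <= gap:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def per_bp_state_fractions(targets, segmentation_rows, chrom_lengths):
    """Brute-force per-base-pair labeling (only usable on tiny genomes)."""
    labels = {}
    for chrom, length in chrom_lengths.items():
        labels[chrom] = np.array(["Unannotated"] * length, dtype=object)
    for chrom, s, e, state in segmentation_rows:
        labels[chrom][s:e] = state
    target_mask = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    for chrom, s, e in targets:
        target_mask[chrom][s:e] = True
    t_counts, g_counts = {}, {}
    for chrom in chrom_lengths:
        for lab in np.unique(labels[chrom]):
            sel = labels[chrom] == lab
            g_counts[lab] = g_counts.get(lab, 0) + int(sel.sum())
            t_counts[lab] = t_counts.get(lab, 0) + int((sel & target_mask[chrom]).sum())
    t_total = sum(t_counts.values())
    g_total = sum(g_counts.values())
    return (
        {k: v / t_total for k, v in t_counts.items() if t_total},
        {k: v / g_total for k, v in g_counts.items()},
    )


# --- statistics --------------------------------------------------------------


def welch_formula(a, b):
    """Closed-form Welch t statistic and Welch–Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def hypergeom_tail_enumeration(q, m, n_total, k):
    """P(X > q) by direct summation of C(m,i) C(n_total-m, k-i) / C(n_total, k)."""
    denom = comb(n_total, k)
    total = 0
    for i in range(q + 1, min(m, k) + 1):
        if k - i <= n_total - m:
            total += comb(m, i) * comb(n_total - m, k - i)
    return total / denom


def mwu_enumeration(x, y):
    """Exact two-sided Mann–Whitney p for tie-free samples, by enumerating
    every assignment of the pooled ranks to group 1."""
    n1, n2 = len(x), len(y)
    pooled = sorted(list(x) + list(y))
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank_of[v] for v in x) - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    hits = total = 0
    ranks = list(range(1, n1 + n2 + 1))
    for subset in combinations(ranks, n1):
        u = sum(subset) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return u_obs, hits / total


def fisher_yates_reference(items, rng):
    """Durstenfeld shuffle consuming the same rng stream as the package."""
    items = list(items)
    for i in range(len(items) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        items[i], items[j] = items[j], items[i]
    return items
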