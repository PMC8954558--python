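"""Resampling statistics for srRNA validation.

* within-read Fisher–Yates (Durstenfeld) shuffling, conserving the multiset
  of (base, quality) pairs of each read, to build a permutation null for the
  whole mapping pipeline;
* interval Jaccard and hypergeometric gene-set overlap;
* Mann–Whitney U with midranks, tie-corrected normal approximation with
  continuity correction, and exact enumeration for small tie-free samples;
* Monte-Carlo calibrations of the U-test's type-I error on expression-like
  (zero-inflated, heavy-tailed) data, and the averaged random expression
  subset used for display alongside the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats as sps

from srrna_scout.core import SmallRead


# ---------------------------------------------------------------------------
# read shuffling and permutation trials
# ---------------------------------------------------------------------------


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def shuffle_read(read: SmallRead, rng) -> SmallRead:
    """Durstenfeld Fisher–Yates shuffle of the read's (base, quality) pairs.

    Base composition and base-quality pairing are conserved exactly; only
    the order is randomized.  The read id is preserved.
    """
    rng = _as_rng(rng)
    seq = list(read.sequence)
    quals = list(read.qualities)
    for i in range(len(seq) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        seq[i], seq[j] = seq[j], seq[i]
        quals[i], quals[j] = quals[j], quals[i]
    return SmallRead(read.read_id, "".join(seq), tuple(quals))


@dataclass(frozen=True)
class PermutationResult:
    """Summary of one shuffled-reads rerun of the mapping pipeline."""

    trial_id: int
    n_mapped_reads: int
    n_mapped_regions: int
    n_region_intersections_with_observed: int
    jaccard: float
    n_overlap_genes: int
    hypergeom_p: float
    correlation_z: float
    correlation_p: float


def _binned_coverage(
    regions: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    bin_width: int,
) -> np.ndarray:
    chunks = []
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for chrom, s, e in regions:
        by_chrom[chrom].append((s, e))
    for chrom in sorted(chrom_lengths):
        n_bins = -(-chrom_lengths[chrom] // bin_width)
        cov = np.zeros(n_bins)
        for s, e in by_chrom[chrom]:
            lo, hi = s // bin_width, (e - 1) // bin_width
            for b in range(lo, hi + 1):
                cov[b] += min(e, (b + 1) * bin_width) - max(s, b * bin_width)
        chunks.append(cov)
    return np.concatenate(chunks)


def coverage_correlation(
    regions_a: list[tuple[str, int, int]],
    regions_b: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    bin_width: int = 10_000,
) -> tuple[float, float]:
    """Spearman rank correlation between two binned region coverages.

    Returns (z, p) with z from the Fisher transform of the Spearman rho at
    the large-sample normal approximation.  Degenerate (constant) coverage
    vectors yield (0, 1).
    """
    a = _binned_coverage(regions_a, chrom_lengths, bin_width)
    b = _binned_coverage(regions_b, chrom_lengths, bin_width)
    if a.std() == 0 or b.std() == 0 or len(a) < 4:
        return 0.0, 1.0
    rho = sps.spearmanr(a, b).statistic
    if np.isnan(rho):
        return 0.0, 1.0
    rho = float(np.clip(rho, -0.999999, 0.999999))
    z = np.arctanh(rho) * sqrt((len(a) - 3) / 1.06)
    return float(z), float(2 * sps.norm.sf(abs(z)))


def permutation_trial(
    reads: list[SmallRead],
    rdna_index,
    genome_index,
    genes,
    observed_records,
    rng,
    trial_id: int = 0,
    rdna_max_mismatch: int = 2,
    genome_max_mismatch: int = 1,
    trim_params: dict | None = None,
    universe_size: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
    bin_width: int = 10_000,
) -> PermutationResult:
    """Shuffle every read within itself, rerun the full isolation pipeline,
    and compare the permuted mappings with the observed ones.

    Shuffling destroys contiguous homology while conserving composition, so
    a specific mapping signal collapses while a compositional artifact would
    survive.  ``universe_size`` (default: number of annotated genes) is the
    population for the hypergeometric overlap p-value.
    """
    from srrna_scout.pipeline import (
        assign_target_genes,
        build_mapping_table,
        merge_regions,
        select_rdna_reads,
    )
    from srrna_scout.qc import deduplicate, trim_dataset

    rng = _as_rng(rng)
    shuffled = [shuffle_read(r, rng) for r in reads]
    trimmed, _ = trim_dataset(shuffled, **(trim_params or {}))
    selected, _ = select_rdna_reads(trimmed, rdna_index, rdna_max_mismatch)
    unique = deduplicate(selected)
    copy_counts = {u.representative.read_id: u.copy_count for u in unique}
    aligned = []
    from srrna_scout.align import align_read

    for u in unique:
        aln = align_read(u.representative, genome_index, genome_max_mismatch)
        if aln is not None:
            aligned.append(aln)
    records = build_mapping_table(aligned, copy_counts=copy_counts)
    n_mapped_reads = sum(r.read_count for r in records)
    perm_regions = merge_regions(records)
    obs_regions = merge_regions(observed_records)
    n_intersections = _count_region_intersections(perm_regions, obs_regions)
    jac = jaccard_intervals(perm_regions, obs_regions)
    perm_genes = {t.gene.gene_id for t in assign_target_genes(records, genes)}
    obs_genes = {t.gene.gene_id for t in assign_target_genes(list(observed_records), genes)}
    n_overlap = len(perm_genes & obs_genes)
    universe = universe_size if universe_size is not None else len(genes)
    if perm_genes and obs_genes:
        hyper_p = hypergeom_overlap_p(n_overlap - 1, len(obs_genes), universe, len(perm_genes))
    else:
        hyper_p = 1.0
    lengths = chrom_lengths or {}
    if not lengths:
        for name, seq in genome_index.sequences.items():
            lengths[name] = len(seq)
    z, p = coverage_correlation(
        [(r.chrom, r.start, r.end) for r in observed_records],
        [(r.chrom, r.start, r.end) for r in records],
        lengths,
        bin_width,
    )
    return PermutationResult(
        trial_id=trial_id,
        n_mapped_reads=n_mapped_reads,
        n_mapped_regions=len(perm_regions),
        n_region_intersections_with_observed=n_intersections,
        jaccard=jac,
        n_overlap_genes=n_overlap,
        hypergeom_p=hyper_p,
        correlation_z=z,
        correlation_p=p,
    )


def _count_region_intersections(
    regions_a: list[tuple[str, int, int]], regions_b: list[tuple[str, int, int]]
) -> int:
    """Number of regions in ``regions_a`` overlapping any region of ``regions_b``."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in regions_b:
        by_chrom.setdefault(chrom, []).append((s, e))
    count = 0
    for chrom, s, e in regions_a:
        for bs, be in by_chrom.get(chrom, ()):
            if s < be and bs < e:
                count += 1
                break
    return count


# ---------------------------------------------------------------------------
# interval and gene-set overlap statistics
# ---------------------------------------------------------------------------


def _merge_by_chrom(intervals) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = {}
    for chrom, ivs in by_chrom.items():
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = [(s, e) for s, e in merged]
    return out


def jaccard_intervals(set_a, set_b) -> float:
    """Total intersection bp / total union bp of two genomic interval sets.

    Each set is merged internally first; an empty union gives 0.
    """
    a, b = _merge_by_chrom(set_a), _merge_by_chrom(set_b)
    inter = 0
    bp_a = sum(e - s for ivs in a.values() for s, e in ivs)
    bp_b = sum(e - s for ivs in b.values() for s, e in ivs)
    for chrom in set(a) & set(b):
        ia, ib = a[chrom], b[chrom]
        i = j = 0
        while i < len(ia) and j < len(ib):
            lo = max(ia[i][0], ib[j][0])
            hi = min(ia[i][1], ib[j][1])
            if hi > lo:
                inter += hi - lo
            if ia[i][1] <= ib[j][1]:
                i += 1
            else:
                j += 1
    union = bp_a + bp_b - inter
    return inter / union if union else 0.0


def hypergeom_overlap_p(
    overlap_exceeding: int, set_a_size: int, universe: int, set_b_size: int
) -> float:
    """P(X > overlap_exceeding) for X ~ Hypergeometric(universe, set_a, set_b).

    The R equivalent is ``phyper(q, m, n - m, k, lower.tail = FALSE)`` with
    q = overlap_exceeding, m = set_a_size, n = universe, k = set_b_size.
    """
    if not (0 <= set_a_size <= universe and 0 <= set_b_size <= universe):
        raise ValueError("set sizes must lie within [0, universe]")
    if overlap_exceeding < -1:
        raise ValueError("overlap_exceeding must be >= -1")
    return float(sps.hypergeom.sf(overlap_exceeding, universe, set_a_size, set_b_size))


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------


def _mwu_exact_p(n1: int, n2: int, u_obs: float, two_sided: bool) -> float:
    """Exact p by enumerating all C(n1+n2, n1) group labelings (tie-free input)."""
    ranks = np.arange(1, n1 + n2 + 1)
    center = n1 * n2 / 2
    hits = 0
    total = comb(n1 + n2, n1)
    for subset in combinations(range(n1 + n2), n1):
        u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2
        if two_sided:
            hits += abs(u - center) >= abs(u_obs - center) - 1e-12
        else:
            hits += u <= u_obs + 1e-12
    return hits / total


def mannwhitney_u(x, y, two_sided: bool = True) -> tuple[float, float]:
    """Mann–Whitney U-test (U of x against y).

    U is computed from midrank sums.  For tie-free samples with
    n1 + n2 <= 12 the two-sided p-value is exact (full enumeration of
    labelings); otherwise the normal approximation with tie-corrected
    variance and a 0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    has_ties = len(np.unique(combined)) < n1 + n2
    if not has_ties and n1 + n2 <= 12:
        return u, min(1.0, _mwu_exact_p(n1, n2, u, two_sided))

    n = n1 + n2
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float((tie_counts.astype(float) ** 3 - tie_counts).sum())
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u, 1.0
    diff = u - mu
    cc = 0.5 if diff != 0 else 0.0
    z = (diff - np.sign(diff) * cc) / sqrt(var)
    p = 2 * sps.norm.sf(abs(z)) if two_sided else sps.norm.sf(z)
    return u, float(min(1.0, p))


# ---------------------------------------------------------------------------
# Monte-Carlo calibrations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McCalibration:
    """Empirical type-I error of the U-test under a constructed true null."""

    n_reps: int
    alpha: float
    rejection_fraction: float
    mode: str  # "equal_subsets" | "full_vs_subset"
    seed: int | None = None


def mc_type1_equal_subsets(
    values,
    subset_size: int = 1575,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    rng=None,
) -> McCalibration:
    """Type-I error when two disjoint equal-size subsets of one shuffled
    vector are compared by the two-sided Mann–Whitney U-test.

    Each repetition shuffles the values and takes the first and second
    ``subset_size`` entries (disjoint by construction).
    """
    values = np.asarray(values, dtype=float)
    if 2 * subset_size > len(values):
        raise ValueError("2 * subset_size must not exceed the number of values")
    rng = _as_rng(rng)
    rejections = 0
    for _ in range(n_reps):
        perm = rng.permutation(values)
        _, p = mannwhitney_u(perm[:subset_size], perm[subset_size : 2 * subset_size])
        if p < alpha:
            rejections += 1
    return McCalibration(n_reps, alpha, rejections / n_reps, "equal_subsets")


def mc_type1_full_vs_subset(
    values,
    subset_size: int = 1575,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    rng=None,
) -> McCalibration:
    """Type-I error when a random subset is tested against the full vector
    it was drawn from (the subset overlaps the full set by construction)."""
    values = np.asarray(values, dtype=float)
    if subset_size > len(values):
        raise ValueError("subset_size must not exceed the number of values")
    rng = _as_rng(rng)
    rejections = 0
    for _ in range(n_reps):
        subset = values[rng.permutation(len(values))[:subset_size]]
        _, p = mannwhitney_u(subset, values)
        if p < alpha:
            rejections += 1
    return McCalibration(n_reps, alpha, rejections / n_reps, "full_vs_subset")


def mc_subset_vs_random(
    expression: dict[str, float],
    focal_genes: list[str],
    n_reps: int = 10_000,
    alpha: float = 1e-4,
    rng=None,
) -> tuple[float, float]:
    """Focal gene set vs equally sized random gene sets, by Mann–Whitney.

    Returns (max p over repetitions, fraction of repetitions with p < alpha).
    """
    import pandas as pd

    if isinstance(expression, pd.DataFrame):
        expression = dict(zip(expression["gene_id"], expression["tpm"]))
    missing = [g for g in focal_genes if g not in expression]
    if missing:
        raise KeyError(f"focal genes missing from the expression table: {missing}")
    rng = _as_rng(rng)
    genes = np.array(sorted(expression))
    all_values = np.array([expression[g] for g in genes], dtype=float)
    focal_values = np.array([expression[g] for g in focal_genes], dtype=float)
    k = len(focal_genes)
    max_p, rejections = 0.0, 0
    for _ in range(n_reps):
        idx = rng.permutation(len(genes))[:k]
        _, p = mannwhitney_u(focal_values, all_values[idx])
        max_p = max(max_p, p)
        if p < alpha:
            rejections += 1
    return max_p, rejections / n_reps


def averaged_random_subset(
    values, subset_size: int = 1575, n_trials: int = 10_000, rng=None
) -> np.ndarray:
    """Element-wise average of sorted random subsets (a display dataset).

    Each trial draws ``subset_size`` values without replacement, sorts them
    ascending and accumulates; the mean vector is nondecreasing and converges
    to the expected order statistics of the subsample.
    """
    values = np.asarray(values, dtype=float)
    if subset_size > len(values):
        raise ValueError("subset_size must not exceed the number of values")
    rng = _as_rng(rng)
    acc = np.zeros(subset_size)
    for _ in range(n_trials):
        acc += np.sort(values[rng.permutation(len(values))[:subset_size]])
    return acc / n_trials
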