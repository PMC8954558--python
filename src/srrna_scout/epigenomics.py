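"""Epigenomic context of srRNA targets.

Z-scored signal metaprofiles around anchor midpoints, chromatin-state
composition of target loci against the genomic background (with a Welch
t-test across chromosomes), and classification of transcription start sites
into bidirectional (divergent, < 1 kb apart, opposite strands) and
unidirectional promoters after filtering minor TSSs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# step-function signal tracks
# ---------------------------------------------------------------------------


@dataclass
class SignalTrack:
    """A step-function genomic signal: per chromosome, sorted non-overlapping
    (start, end, value) steps; uncovered positions have value 0."""

    steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_steps(cls, intervals: dict[str, list[tuple[int, int, float]]]) -> "SignalTrack":
        steps = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            values = np.array([v for _, _, v in ivs], dtype=float)
            if np.any(ends <= starts) or np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: track steps must be non-overlapping with end > start")
            steps[chrom] = (starts, ends, values)
        return cls(steps)

    def chrom_length(self, chrom: str) -> int:
        starts, ends, _ = self.steps.get(chrom, (np.array([]), np.array([0]), np.array([])))
        return int(ends[-1]) if len(ends) else 0

    def _cumulative(self, chrom: str) -> np.ndarray:
        starts, ends, values = self.steps[chrom]
        return np.concatenate([[0.0], np.cumsum((ends - starts) * values)])

    def integral_at(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, x) for an array of positions x."""
        if chrom not in self.steps:
            return np.zeros(len(x))
        starts, ends, values = self.steps[chrom]
        cum = self._cumulative(chrom)
        x = np.asarray(x, dtype=np.int64)
        i = np.searchsorted(starts, x, side="right") - 1
        out = np.zeros(len(x))
        inside = i >= 0
        ii = i[inside]
        partial = np.clip(x[inside] - starts[ii], 0, ends[ii] - starts[ii])
        out[inside] = cum[ii] + values[ii] * partial
        return out

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v) in self.steps.items()}
        )

    def shifted(self, offset: float) -> "SignalTrack":
        """Add a constant to the signal over the covered extent."""
        return SignalTrack(
            {c: (s.copy(), e.copy(), v + offset) for c, (s, e, v) in self.steps.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.steps):
            starts, ends, values = self.steps[chrom]
            for s, e, v in zip(starts, ends, values):
                rows.append((chrom, int(s), int(e), float(v)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def coverage_track(
    intervals: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    weights: list[float] | None = None,
) -> SignalTrack:
    """Per-base depth of a set of intervals as a step-function track."""
    deltas: dict[str, np.ndarray] = {c: np.zeros(n + 1) for c, n in chrom_lengths.items()}
    for idx, (chrom, start, end) in enumerate(intervals):
        w = 1.0 if weights is None else weights[idx]
        if chrom not in deltas:
            raise KeyError(f"interval on unknown chromosome {chrom!r}")
        deltas[chrom][start] += w
        deltas[chrom][end] -= w
    steps: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, delta in deltas.items():
        depth = np.cumsum(delta[:-1])
        change = np.flatnonzero(np.diff(depth)) + 1
        bounds = np.concatenate([[0], change, [len(depth)]])
        steps[chrom] = [
            (int(a), int(b), float(depth[a])) for a, b in zip(bounds[:-1], bounds[1:])
        ]
    return SignalTrack.from_steps(steps)


# ---------------------------------------------------------------------------
# metaprofiles
# ---------------------------------------------------------------------------


@dataclass
class MetaProfile:
    """Mean signal in fixed-width bins across windows centred on anchors."""

    bin_size: int
    flank: int
    values: np.ndarray
    n_anchors: int

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin_size

    def to_frame(self) -> pd.DataFrame:
        centers = -self.flank + self.bin_size * (np.arange(self.n_bins) + 0.5)
        return pd.DataFrame({"bin_center": centers, "value": self.values})


def metaprofile(
    track: SignalTrack,
    anchors: list[tuple[str, int]],
    flank: int = 1500,
    bin_size: int = 10,
    zscore: bool = True,
    chrom_lengths: dict[str, int] | None = None,
) -> MetaProfile:
    """Signal metaprofile over ``[mid - flank, mid + flank)`` windows.

    Signal inside each bin is length-weighted by the overlap of track steps
    with the bin; bins are averaged across anchors.  Windows running past a
    chromosome end are clipped, with per-bin denominators adjusted so the
    mean uses only covered length.  With ``zscore`` the profile is centred
    and scaled over its bins; a zero-variance (constant) profile z-scores to
    all zeros rather than raising.
    """
    if not anchors:
        raise ValueError("metaprofile requires at least one anchor")
    if flank % bin_size:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    numer = np.zeros(n_bins)
    denom = np.zeros(n_bins)
    lengths = chrom_lengths or {}
    for chrom, mid in anchors:
        chrom_len = lengths.get(chrom, track.chrom_length(chrom))
        edges = mid - flank + bin_size * np.arange(n_bins + 1)
        clipped = np.clip(edges, 0, chrom_len)
        numer += np.diff(track.integral_at(chrom, clipped))
        denom += np.diff(clipped)
    values = np.divide(numer, denom, out=np.zeros(n_bins), where=denom > 0)
    if zscore:
        sd = values.std()
        values = (values - values.mean()) / sd if sd > 0 else np.zeros(n_bins)
    return MetaProfile(bin_size=bin_size, flank=flank, values=values, n_anchors=len(anchors))


def anchor_midpoints(records) -> list[tuple[str, int]]:
    """Interval midpoints, floor((start + end) / 2), as (chrom, position)."""
    return [(r.chrom, (r.start + r.end) // 2) for r in records]


# ---------------------------------------------------------------------------
# chromatin-state composition
# ---------------------------------------------------------------------------

UNANNOTATED = "Unannotated"


@dataclass
class StateSegmentation:
    """Labeled, per-chromosome non-overlapping genomic intervals."""

    intervals: pd.DataFrame  # columns: chrom, start, end, state

    def __post_init__(self) -> None:
        df = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError(f"{chrom}: state segments overlap")
        self.intervals = df

    @property
    def states(self) -> list[str]:
        return sorted(self.intervals["state"].unique())

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        grp = self.intervals[self.intervals["chrom"] == chrom]
        return grp["start"].to_numpy(), grp["end"].to_numpy(), grp["state"].to_numpy()


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _state_bp_by_chrom(
    targets: list[tuple[str, int, int]],
    states: StateSegmentation,
    chrom_lengths: dict[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome bp of target∩state and of state (plus Unannotated)."""
    labels = states.states + [UNANNOTATED]
    target_bp = pd.DataFrame(0, index=sorted(chrom_lengths), columns=labels, dtype=float)
    genome_bp = pd.DataFrame(0, index=sorted(chrom_lengths), columns=labels, dtype=float)
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for chrom, s, e in targets:
        by_chrom[chrom].append((s, e))
    for chrom, length in chrom_lengths.items():
        starts, ends, labs = states.arrays(chrom)
        genome_bp.loc[chrom, UNANNOTATED] = length - (ends - starts).sum()
        for s, e, lab in zip(starts, ends, labs):
            genome_bp.loc[chrom, lab] += e - s
        for ts, te in _merge(by_chrom[chrom]):
            covered = 0
            lo = np.searchsorted(ends, ts, side="right")
            hi = np.searchsorted(starts, te, side="left")
            for i in range(lo, hi):
                ov = min(te, ends[i]) - max(ts, starts[i])
                if ov > 0:
                    target_bp.loc[chrom, labs[i]] += ov
                    covered += ov
            target_bp.loc[chrom, UNANNOTATED] += (te - ts) - covered
    return target_bp, genome_bp


def state_composition(
    targets: list[tuple[str, int, int]],
    states: StateSegmentation,
    genome_lengths: dict[str, int],
) -> pd.DataFrame:
    """Fraction of target bp and of genome bp per chromatin state.

    Target intervals are merged before counting so overlapping mappings do
    not double-count.  Base pairs not covered by the segmentation fall into
    an extra ``Unannotated`` bucket; each fraction column sums to 1.
    """
    target_bp, genome_bp = _state_bp_by_chrom(targets, states, genome_lengths)
    t, g = target_bp.sum(axis=0), genome_bp.sum(axis=0)
    out = pd.DataFrame(
        {
            "target_fraction": t / t.sum() if t.sum() else t,
            "genome_fraction": g / g.sum(),
        }
    )
    out.index.name = "state"
    return out


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def state_welch_test(
    targets: list[tuple[str, int, int]],
    states: StateSegmentation,
    genome_lengths: dict[str, int],
) -> pd.DataFrame:
    """Welch two-sample t-test per state, across per-chromosome fractions.

    For each state the replicates are the per-chromosome target fraction and
    the per-chromosome genome fraction of that state; two-sided p-values use
    the Welch–Satterthwaite degrees of freedom.  Chromosomes with no target
    bp contribute only to the genome side being compared against, so both
    groups use chromosomes carrying targets.
    """
    if len(genome_lengths) < 2:
        raise ValueError("per-chromosome Welch test needs at least 2 chromosomes")
    target_bp, genome_bp = _state_bp_by_chrom(targets, states, genome_lengths)
    t_tot = target_bp.sum(axis=1)
    used = t_tot[t_tot > 0].index
    if len(used) < 2:
        raise ValueError("targets must cover at least 2 chromosomes")
    t_frac = target_bp.loc[used].div(target_bp.loc[used].sum(axis=1), axis=0)
    g_frac = genome_bp.loc[used].div(genome_bp.loc[used].sum(axis=1), axis=0)
    rows = []
    for state in t_frac.columns:
        t, p = _welch(t_frac[state].to_numpy(), g_frac[state].to_numpy())
        rows.append((state, t, p))
    return pd.DataFrame(rows, columns=["state", "t", "p"]).set_index("state")


# ---------------------------------------------------------------------------
# TSS classification
# ---------------------------------------------------------------------------

TSS_COLUMNS = ["gene_id", "chrom", "pos", "strand", "cage_expression"]


def classify_tss(
    tss_table: pd.DataFrame,
    minor_fraction: float = 0.01,
    bidir_max_dist: int = 1000,
) -> pd.DataFrame:
    """Classify TSSs as bidirectional / unidirectional / filtered_minor.

    Per gene, TSSs whose CAGE expression is strictly below ``minor_fraction``
    of the gene's strongest TSS are marked ``filtered_minor``.  Among the
    survivors, a TSS is ``bidirectional`` when an opposite-strand surviving
    TSS lies within ``bidir_max_dist`` bp in divergent orientation (the
    minus-strand TSS at or upstream of the plus-strand TSS, so the two
    transcripts run apart and do not intersect); all other survivors are
    ``unidirectional``.
    """
    df = tss_table.copy().reset_index(drop=True)
    if (df["cage_expression"] < 0).any():
        raise ValueError("cage_expression must be >= 0")
    major = df.groupby("gene_id")["cage_expression"].transform("max")
    minor = df["cage_expression"] < minor_fraction * major
    df["tss_class"] = np.where(minor, "filtered_minor", "unidirectional")

    surv = df[~minor]
    for chrom, grp in surv.groupby("chrom"):
        plus = grp[grp["strand"] == "+"]
        minus = grp[grp["strand"] == "-"]
        if plus.empty or minus.empty:
            continue
        mpos = np.sort(minus["pos"].to_numpy())
        ppos = np.sort(plus["pos"].to_numpy())
        for idx, p in zip(plus.index, plus["pos"]):
            # a divergent partner: minus TSS in [p - bidir_max_dist + 1, p]
            lo = np.searchsorted(mpos, p - bidir_max_dist, side="right")
            hi = np.searchsorted(mpos, p, side="right")
            if hi > lo:
                df.loc[idx, "tss_class"] = "bidirectional"
        for idx, m in zip(minus.index, minus["pos"]):
            lo = np.searchsorted(ppos, m, side="left")
            hi = np.searchsorted(ppos, m + bidir_max_dist, side="left")
            if hi > lo:
                df.loc[idx, "tss_class"] = "bidirectional"
    return df


def tss_metaprofile(
    mapping_records,
    classified_tss: pd.DataFrame,
    chrom_lengths: dict[str, int],
    flank: int = 1500,
    bin_size: int = 10,
    zscore: bool = True,
) -> dict[str, MetaProfile]:
    """srRNA mapping-coverage metaprofiles around each surviving TSS class."""
    track = coverage_track(
        [(r.chrom, r.start, r.end) for r in mapping_records],
        chrom_lengths,
        weights=[r.read_count for r in mapping_records],
    )
    profiles: dict[str, MetaProfile] = {}
    for cls in ("bidirectional", "unidirectional"):
        grp = classified_tss[classified_tss["tss_class"] == cls]
        if grp.empty:
            warnings.warn(f"no TSS in class {cls!r}; profile skipped", stacklevel=2)
            continue
        anchors = list(zip(grp["chrom"], grp["pos"].astype(int)))
        profiles[cls] = metaprofile(
            track, anchors, flank=flank, bin_size=bin_size, zscore=zscore,
            chrom_lengths=chrom_lengths,
        )
    return profiles
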