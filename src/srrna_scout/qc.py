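"""Quality trimming, exact deduplication and length statistics of small-RNA reads.

Trimming applies, in order, LEADING / TRAILING / SLIDINGWINDOW / MINLEN with
the thresholds used for the srRNA library (18 / 18 / 4:22 / 20).  Rejected
reads are represented by ``None``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from srrna_scout.core import SmallRead, UniqueRead


@dataclass(frozen=True)
class LengthSummary:
    n: int
    min_len: int
    max_len: int
    mean_len: float
    histogram: dict[int, int]


def trim_read(
    read: SmallRead,
    leading_q: int = 18,
    trailing_q: int = 18,
    window: int = 4,
    window_q: float = 22,
    min_len: int = 20,
) -> SmallRead | None:
    """Quality-trim one read; return the trimmed read or None if rejected.

    Steps, applied in order:

    * LEADING — drop 5' bases while their quality is below ``leading_q``.
    * TRAILING — drop 3' bases while their quality is below ``trailing_q``.
    * SLIDINGWINDOW — scan 5'->3'; at the first ``window``-base window whose
      mean quality falls below ``window_q`` the read is cut at the window
      start, then trailing bases below ``window_q`` are stripped so the kept
      part ends on a confident base (this back-trim is what makes trimming
      idempotent).  A read shorter than ``window`` is kept only if its mean
      quality is at least ``window_q``.
    * MINLEN — reject if the final length is below ``min_len``.
    """
    if min(leading_q, trailing_q, window_q, min_len) < 0 or window < 1:
        raise ValueError("trimming thresholds must be >= 0 and window >= 1")
    quals = read.qualities
    n = len(quals)

    lo = 0
    while lo < n and quals[lo] < leading_q:
        lo += 1
    hi = n
    while hi > lo and quals[hi - 1] < trailing_q:
        hi -= 1

    seq, quals = read.sequence[lo:hi], quals[lo:hi]
    m = len(quals)

    if 0 < m < window:
        if sum(quals) < window_q * m:
            seq, quals = "", ()
    else:
        threshold = window_q * window
        running = sum(quals[:window]) if m else 0
        cut = m
        failed = False
        for s in range(m - window + 1):
            if s > 0:
                running += quals[s + window - 1] - quals[s - 1]
            if running < threshold:
                cut, failed = s, True
                break
        if failed:
            while cut > 0 and quals[cut - 1] < window_q:
                cut -= 1
        seq, quals = seq[:cut], quals[:cut]

    if len(seq) < min_len:
        return None
    return SmallRead(read.read_id, seq, quals)


def trim_dataset(
    reads: list[SmallRead], **trim_params
) -> tuple[list[SmallRead], dict[str, int]]:
    """Trim every read; return surviving reads (input order) and counts."""
    kept = []
    for read in reads:
        trimmed = trim_read(read, **trim_params)
        if trimmed is not None:
            kept.append(trimmed)
    counts = {"input": len(reads), "kept": len(kept), "rejected": len(reads) - len(kept)}
    return kept, counts


def _end_trim(read: SmallRead, q: int) -> SmallRead:
    quals = read.qualities
    lo, hi = 0, len(quals)
    while lo < hi and quals[lo] < q:
        lo += 1
    while hi > lo and quals[hi - 1] < q:
        hi -= 1
    return SmallRead(read.read_id, read.sequence[lo:hi], quals[lo:hi])


def deduplicate(reads: list[SmallRead], end_trim_q: int = 18) -> list[UniqueRead]:
    """Collapse exact sequence copies after trimming low-quality ends.

    Each read is first end-trimmed (bases below ``end_trim_q`` stripped from
    both ends); reads whose trimmed sequences are byte-identical collapse to
    one :class:`UniqueRead` whose representative is the first occurrence.
    Reads that are empty after end-trimming are dropped, so the copy counts
    sum to the number of reads surviving the end-trim.
    """
    buckets: dict[str, list] = {}
    for read in reads:
        trimmed = _end_trim(read, end_trim_q)
        if not trimmed.sequence:
            continue
        entry = buckets.get(trimmed.sequence)
        if entry is None:
            buckets[trimmed.sequence] = [trimmed, 1]
        else:
            entry[1] += 1
    return [UniqueRead(rep, count) for rep, count in buckets.values()]


def length_summary(reads: list[SmallRead]) -> LengthSummary:
    """Integer length histogram with min/max/mean."""
    if not reads:
        raise ValueError("length_summary requires at least one read")
    lengths = [len(r) for r in reads]
    hist = dict(sorted(Counter(lengths).items()))
    return LengthSummary(
        n=len(lengths),
        min_len=min(lengths),
        max_len=max(lengths),
        mean_len=sum(lengths) / len(lengths),
        histogram=hist,
    )
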