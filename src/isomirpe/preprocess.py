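"""Adapter trimming and paired-read overlap merging.

Trimming removes the 3' adapter (and everything after it) from a read using
a semi-global alignment with unit-cost edits, accepting the best occurrence
with an error rate at most ``max_error`` over at least ``min_overlap``
aligned bases; reads without an acceptable match are returned unchanged.

Merging reverse-complements R2, scans all overlap offsets between the two
mates from full containment down to ``min_overlap``, picks the overlap with
the smallest mismatch fraction (ties go to the longer overlap), and joins
when that fraction is at most ``pct_diff``.  The consensus takes the
higher-quality base at disagreeing positions (ties go to R1).  A 0%
threshold therefore only ever joins perfectly agreeing pairs, which is the
error-suppression mechanism the paired-end analysis mode relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

from .readsim import FastqRead, revcomp


@dataclass(frozen=True)
class TrimResult:
    sequence: str
    quality: str
    trimmed: bool
    adapter_start: int | None  # position at which the read was cut


@dataclass(frozen=True)
class MergedRead:
    pair_id: str
    status: str  # "joined" | "unjoined"
    consensus_seq: str = ""
    consensus_qual: str = ""
    overlap_len: int = 0
    n_mismatch: int = 0

    @property
    def joined(self) -> bool:
        return self.status == "joined"


def quality_trim_3p(seq: str, qual: str, cutoff: int) -> tuple[str, str]:
    """BWA-style 3' quality trimming: cut where the running sum of
    ``cutoff - q`` from the 3' end is maximal."""
    if cutoff <= 0 or not seq:
        return seq, qual
    best_sum, running, cut = 0, 0, len(seq)
    for i in range(len(seq) - 1, -1, -1):
        running += cutoff - (ord(qual[i]) - 33)
        if running > best_sum:
            best_sum, cut = running, i
        if running < 0:
            break
    return seq[:cut], qual[:cut]


def _semi_global_candidates(seq: str, adapter: str):
    """Yield (start, matched_len, errors) for adapter occurrences in ``seq``.

    Alignments are adapter vs read with a free read prefix (the retained
    part), unit-cost substitutions/insertions/deletions, and either the full
    adapter matched internally or an adapter prefix running off the read 3'
    end.  ``matched_len`` is the length of the matched read region.
    """
    n, m = len(seq), len(adapter)
    # D[i][k]: min edits aligning adapter[:i] against seq ending at k,
    # start free in seq; S tracks the alignment start.
    prev_d = [0] * (n + 1)
    prev_s = list(range(n + 1))
    last_row = (prev_d, prev_s)
    for i in range(1, m + 1):
        cur_d = [i] * (n + 1)
        cur_s = [0] * (n + 1)
        a = adapter[i - 1]
        for k in range(1, n + 1):
            sub = prev_d[k - 1] + (a != seq[k - 1])
            dele = prev_d[k] + 1  # adapter base unmatched (gap in read)
            ins = cur_d[k - 1] + 1  # read base unmatched (gap in adapter)
            best = sub
            start = prev_s[k - 1]
            if dele < best:
                best, start = dele, prev_s[k]
            if ins < best:
                best, start = ins, cur_s[k - 1]
            cur_d[k], cur_s[k] = best, start
        # adapter prefix aligned to the read 3' end (read-through cut short)
        yield cur_s[n], n - cur_s[n], cur_d[n]
        prev_d, prev_s = cur_d, cur_s
        last_row = (cur_d, cur_s)
    d, s = last_row
    for k in range(1, n + 1):  # full adapter matched internally
        yield s[k], k - s[k], d[k]


def trim_adapter(
    seq: str,
    qual: str,
    adapter: str,
    max_error: float = 0.10,
    min_overlap: int = 3,
    quality_cutoff: int = 0,
) -> TrimResult:
    """Trim a 3' adapter from a read; returns the read unchanged on no match."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq, qual = quality_trim_3p(seq, qual, quality_cutoff)
    if not seq:
        return TrimResult(seq, qual, False, None)

    # fast path: exact full-adapter occurrence, or exact adapter prefix at
    # the read 3' end (covers all error-free reads)
    j = seq.find(adapter)
    if j == -1:
        for k in range(min(len(adapter) - 1, len(seq)), min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                j = len(seq) - k
                break
    if j != -1 and len(seq) - j >= min_overlap:
        return TrimResult(seq[:j], qual[:j], True, j)

    best: tuple[float, int, int] | None = None  # (rate, -matched_len, start)
    for start, matched_len, errors in _semi_global_candidates(seq, adapter):
        if matched_len < min_overlap:
            continue
        rate = errors / matched_len
        if rate > max_error:
            continue
        key = (rate, -matched_len, start)
        if best is None or key < best:
            best = key
    if best is None:
        return TrimResult(seq, qual, False, None)
    start = best[2]
    return TrimResult(seq[:start], qual[:start], True, start)


def merge_pair(
    r1: FastqRead,
    r2: FastqRead,
    min_overlap: int = 6,
    pct_diff: float = 0.0,
) -> MergedRead:
    """Overlap-join an adapter-trimmed read pair (R2 reverse-complemented).

    The overlap is modeled as a suffix of R1 against a prefix of the
    reverse-complemented R2 (full containment when the trimmed mates span
    the same insert).  Comparison against ``pct_diff`` uses the exact
    mismatch fraction, no rounding.
    """
    s1, q1 = r1.sequence, r1.quality
    s2 = revcomp(r2.sequence)
    q2 = r2.quality[::-1]
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0 or min(n1, n2) < min_overlap:
        return MergedRead(r1.name, "unjoined")

    best: tuple[float, int, int] | None = None  # (frac, -L, mismatches)
    for length in range(min(n1, n2), min_overlap - 1, -1):
        a = s1[n1 - length :]
        b = s2[:length]
        if a == b:
            mism = 0
        else:
            mism = sum(x != y for x, y in zip(a, b))
        frac = mism / length
        if best is None or (frac, -length) < (best[0], best[1]):
            best = (frac, -length, mism)
        if best[0] == 0.0:
            break  # a longer zero-mismatch overlap always wins ties
    frac, neg_len, mism = best
    length = -neg_len
    if frac > pct_diff:
        return MergedRead(r1.name, "unjoined", overlap_len=length, n_mismatch=mism)

    off = n1 - length
    cons, cons_q = [s1[:off]], [q1[:off]]
    for i in range(length):
        b1, b2 = s1[off + i], s2[i]
        p1, p2 = ord(q1[off + i]) - 33, ord(q2[i]) - 33
        if b1 == b2:
            cons.append(b1)
            cons_q.append(chr(33 + max(p1, p2)))
        else:
            cons.append(b2 if p2 > p1 else b1)
            cons_q.append(chr(33 + max(2, abs(p1 - p2))))
    cons.append(s2[length:])
    cons_q.append(q2[length:])
    return MergedRead(
        r1.name,
        "joined",
        consensus_seq="".join(cons),
        consensus_qual="".join(cons_q),
        overlap_len=length,
        n_mismatch=mism,
    )
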