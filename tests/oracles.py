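"""Independent brute-force oracles used to validate the optimized paths.

Everything here is written as direct enumeration with no shared code with
the package implementation: plain edit-distance recursions, exhaustive
overlap scans, forward generation of isomiR decompositions, and an explicit
running-sum walk for enrichment scores.
"""

from __future__ import annotations

import itertools
from functools import lru_cache


# --- adapter trimming ------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
        )

    return d(len(a), len(b))


def brute_trim_candidates(seq: str, adapter: str):
    """All (start, matched_len, errors) alignments of the adapter in seq:
    full adapter against any read window ending anywhere, or any adapter
    prefix against a read window running to the read 3' end."""
    n, m = len(seq), len(adapter)
    for start in range(n):
        for end in range(start + 1, n + 1):
            yield start, end - start, levenshtein(seq[start:end], adapter)
        for a in range(1, m):
            yield start, n - start, levenshtein(seq[start:], adapter[:a])


def brute_trim_point(
    seq: str, adapter: str, max_error: float = 0.10, min_overlap: int = 3
) -> int | None:
    """Position at which the read should be cut, or None for no trim."""
    best = None
    for start, matched_len, errors in brute_trim_candidates(seq, adapter):
        if matched_len < min_overlap or errors / matched_len > max_error:
            continue
        key = (errors / matched_len, -matched_len, start)
        if best is None or key < best:
            best = key
    return None if best is None else best[2]


# --- pair merging ----------------------------------------------------------

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def brute_merge_decision(
    s1: str, s2: str, min_overlap: int = 6, pct_diff: float = 0.0
):
    """(joined, overlap_len, n_mismatch) by exhaustive overlap enumeration.

    ``s2`` is the raw R2 (reverse-complemented here); overlap = suffix of
    R1 vs prefix of rc(R2); best overlap minimizes mismatch fraction, ties
    to the longer overlap.
    """
    t2 = rc(s2)
    n1, n2 = len(s1), len(t2)
    if min(n1, n2) < min_overlap:
        return False, 0, 0
    scored = []
    for length in range(min_overlap, min(n1, n2) + 1):
        mism = sum(
            x != y for x, y in zip(s1[n1 - length :], t2[:length])
        )
        scored.append((mism / length, -length, mism))
    frac, neg_len, mism = min(scored)
    return frac <= pct_diff, -neg_len, mism


# --- isomiR decomposition --------------------------------------------------

def enumerate_isoforms(
    mature: str,
    flank5: str,
    flank3: str,
    max_shift: int = 3,
    max_add: int = 3,
    max_snv: int = 1,
):
    """Forward-generate every (sequence, n_edits) a single anchor can
    explain, yielding (sequence, edits, class tuple)."""
    M = len(mature)
    bases = "ACGT"
    for s5 in range(-max_shift, max_shift + 1):
        if s5 > len(flank5) or -s5 >= M:
            continue
        for s3 in range(-max_shift, max_shift + 1):
            if s3 > len(flank3) or -s3 >= M:
                continue
            trim5, trim3 = max(0, -s5), max(0, -s3)
            if trim5 + trim3 >= M:
                continue
            core = (
                (flank5[len(flank5) - s5 :] if s5 > 0 else "")
                + mature[trim5 : M - trim3]
                + (flank3[:s3] if s3 > 0 else "")
            )
            if trim3 > 0:
                templated_next = mature[M - trim3]
            elif s3 < len(flank3):
                templated_next = flank3[s3]
            else:
                templated_next = None
            tails = [""]
            for n_add in range(1, max_add + 1):
                for tail in map("".join, itertools.product(bases, repeat=n_add)):
                    if templated_next is not None and tail[0] == templated_next:
                        continue
                    tails.append(tail)
            # snv placement on the mature-aligned part of the core
            ext5 = max(0, s5)
            mature_span = range(ext5, ext5 + (M - trim5 - trim3))
            variants = [(core, 0)]
            if max_snv >= 1:
                for i in mature_span:
                    for b in bases:
                        if b == core[i]:
                            continue
                        variants.append((core[:i] + b + core[i + 1 :], 1))
            for var, n_snv in variants:
                for tail in tails:
                    edits = abs(s5) + abs(s3) + len(tail) + n_snv
                    yield var + tail, edits


def brute_min_edits(seq: str, anchors, **limits) -> tuple[int | None, int]:
    """(minimum edit count over all anchors, number of anchors attaining it)
    for a sequence; (None, 0) when no anchor explains it."""
    best = None
    attained = 0
    for anchor in anchors:
        per_anchor = None
        for cand, edits in enumerate_isoforms(
            anchor.mature_seq, anchor.flank5, anchor.flank3, **limits
        ):
            if cand == seq and (per_anchor is None or edits < per_anchor):
                per_anchor = edits
        if per_anchor is None:
            continue
        if best is None or per_anchor < best:
            best, attained = per_anchor, 1
        elif per_anchor == best:
            attained += 1
    return best, attained


# --- enrichment running sum ------------------------------------------------

def brute_running_extrema(metrics, hit_flags, p: float):
    """Explicit running-sum walk; returns (max, min) of the running sum."""
    n = len(metrics)
    n_hit = sum(hit_flags)
    weights = [abs(m) ** p for m in metrics]
    total = sum(w for w, h in zip(weights, hit_flags) if h)
    running, hi, lo = 0.0, 0.0, 0.0
    for i in range(n):
        if hit_flags[i]:
            running += (weights[i] / total) if total > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        hi = max(hi, running)
        lo = min(lo, running)
    return hi, lo


def brute_enrichment_score(metrics, hit_flags, p: float):
    """Signed max-magnitude running-sum value (positive wins exact ties)."""
    hi, lo = brute_running_extrema(metrics, hit_flags, p)
    return hi if abs(hi) >= abs(lo) else lo


def assert_es_matches(got, metrics, hit_flags, p, tol=1e-9):
    """ES must equal the larger-magnitude running extremum; when the two
    extrema tie in magnitude (to within floating-point noise) either sign
    is a correct answer."""
    hi, lo = brute_running_extrema(metrics, hit_flags, p)
    if abs(hi) > abs(lo) + tol:
        assert abs(got - hi) < tol, (got, hi, lo)
    elif abs(lo) > abs(hi) + tol:
        assert abs(got - lo) < tol, (got, hi, lo)
    else:
        assert abs(abs(got) - abs(hi)) < tol, (got, hi, lo)
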