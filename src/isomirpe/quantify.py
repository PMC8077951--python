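"""Expression matrices and single-read vs paired-end mode comparison.

Rows of an expression matrix are unique sequences indexed as
``<miRNA>|<variant label>|<UID>`` so that every aggregation level (mature
miRNA, isomiR class, length-variant cluster, or raw sequence) can be parsed
back out of the index.  The four analysis modes compared throughout are
SR1 (forward single reads), SR2 (reverse-complemented reverse reads),
PE_0 (merged pairs, 0% mismatch tolerance) and PE_8 (merged pairs, 8%).

The false-positive rule: when a single read supports an isomiR call but the
merged consensus of the same physical read pair is called as the canonical
sequence or a different variant, the single-read count is evidence of a
sequencing error, not biology, and is removed.  Pairs whose mates could not
be merged carry no evidence either way and are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import IsomiRCall, class_of_label, read_mirgff3

MODES = ("SR1", "SR2", "PE_0", "PE_8")

LEVELS = ("sequence", "class", "length_cluster", "mirna")


class MatrixError(ValueError):
    pass


def row_key(call: IsomiRCall) -> str:
    return f"{call.mirna}|{call.variant_label}|{call.uid}"


def parse_row_key(key: str) -> tuple[str, str, str]:
    parts = key.split("|")
    if len(parts) != 3:
        raise MatrixError(f"unparseable row index {key!r}")
    return parts[0], parts[1], parts[2]


def class_of_key(key: str) -> str:
    return class_of_label(parse_row_key(key)[1])


@dataclass
class MatrixBundle:
    """A sequence-level matrix plus its UID->sequence companion table and a
    report of sequence-level duplicates dropped from it."""

    matrix: pd.DataFrame
    uid_to_sequence: pd.DataFrame
    dropped: pd.DataFrame


def matrix_from_counts(
    per_sample: Mapping[str, Mapping[str, int]],
) -> pd.DataFrame:
    """Union per-sample {row key: count} maps into one integer matrix."""
    df = pd.DataFrame(per_sample).fillna(0).astype(int)
    df = df.sort_index()
    df.index.name = "index"
    return df


def _drop_sequence_duplicates(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows whose underlying sequence (UID) is claimed by more than one
    (miRNA, variant) assignment; such duplicated entries are discarded."""
    uids = [parse_row_key(k)[2] for k in df.index]
    counts = pd.Series(uids, index=df.index).value_counts()
    dup_uids = set(counts[counts > 1].index)
    if not dup_uids:
        return df, pd.DataFrame(columns=["index", "uid"])
    mask = [u in dup_uids for u in uids]
    dropped = pd.DataFrame(
        {"index": df.index[mask], "uid": [u for u in uids if u in dup_uids]}
    )
    return df.loc[[not m for m in mask]], dropped


def build_matrix(paths: Sequence[str | Path]) -> MatrixBundle:
    """Build a sequence-level matrix from per-sample miR.gff3 files.

    Rows are unioned across samples with zero fill; entries whose sequence
    is claimed by multiple (miRNA, variant) assignments are dropped and
    reported; a UID -> sequence companion table is produced.  Conflicting
    (UID, sequence) pairs across files are an error.
    """
    if not paths:
        raise MatrixError("need at least one miR.gff3 file")
    per_sample: dict[str, dict[str, int]] = {}
    uid_seq: dict[str, str] = {}
    for path in paths:
        entries, samples = read_mirgff3(path)
        if len(samples) != 1:
            raise MatrixError(f"{path}: expected a single-sample file")
        sample = samples[0]
        counts = per_sample.setdefault(sample, {})
        for e in entries:
            known = uid_seq.get(e.uid)
            if known is not None and known != e.sequence:
                raise MatrixError(
                    f"{path}: UID {e.uid} maps to conflicting sequences"
                )
            uid_seq[e.uid] = e.sequence
            key = f"{e.name}|{e.variant}|{e.uid}"
            counts[key] = counts.get(key, 0) + e.expression[0]
    df = matrix_from_counts(per_sample)
    df, dropped = _drop_sequence_duplicates(df)
    companion = pd.DataFrame(
        sorted(uid_seq.items()), columns=["uid", "sequence"]
    )
    return MatrixBundle(df, companion, dropped)


def aggregate(matrix: pd.DataFrame, level: str) -> pd.DataFrame:
    """Aggregate a sequence-level matrix to class / length_cluster / mirna.

    Row keys become ``<miRNA>_<class>``, ``<miRNA>_<variant label>`` or
    ``<miRNA>``; column sums are preserved exactly.
    """
    if level == "sequence":
        return matrix.copy()
    if level not in LEVELS:
        raise MatrixError(f"unknown aggregation level {level!r}")
    keys = []
    for idx in matrix.index:
        mirna, label, _uid = parse_row_key(idx)
        if level == "mirna":
            keys.append(mirna)
        elif level == "class":
            keys.append(f"{mirna}_{class_of_label(label)}")
        else:
            keys.append(f"{mirna}_{label}")
    out = matrix.groupby(pd.Index(keys, name="index")).sum().sort_index()
    return out


@dataclass
class ModeComparison:
    """Per-class counts and n-way overlap structure across analysis modes."""

    unique_counts: pd.DataFrame  # class x mode, unique sequences
    read_counts: pd.DataFrame  # class x mode, summed counts
    venn: dict[frozenset, int]  # global partition over all modes
    class_venn: dict[str, dict[frozenset, int]]

    def venn_cell(self, *modes: str) -> int:
        return self.venn.get(frozenset(modes), 0)


def compare_modes(matrices: Mapping[str, pd.DataFrame]) -> ModeComparison:
    """Compare sequence-level matrices across analysis modes (exact sets)."""
    bad = set(matrices) - set(MODES)
    if bad:
        raise MatrixError(f"unknown mode name(s): {sorted(bad)}")
    membership: dict[str, set[str]] = {
        mode: set(df.index[(df.sum(axis=1) > 0)]) for mode, df in matrices.items()
    }
    all_rows = sorted(set().union(*membership.values())) if membership else []
    classes = sorted({class_of_key(k) for k in all_rows})
    uniq = pd.DataFrame(0, index=classes, columns=list(matrices))
    reads = pd.DataFrame(0, index=classes, columns=list(matrices))
    for mode, df in matrices.items():
        for key in membership[mode]:
            uniq.loc[class_of_key(key), mode] += 1
        totals = df.sum(axis=1)
        for key, total in totals.items():
            reads.loc[class_of_key(key), mode] += int(total)
    venn: dict[frozenset, int] = {}
    class_venn: dict[str, dict[frozenset, int]] = {c: {} for c in classes}
    for key in all_rows:
        cell = frozenset(m for m in matrices if key in membership[m])
        venn[cell] = venn.get(cell, 0) + 1
        cv = class_venn[class_of_key(key)]
        cv[cell] = cv.get(cell, 0) + 1
    return ModeComparison(uniq, reads, venn, class_venn)


@dataclass(frozen=True)
class PairTrace:
    """Per read-pair calling outcome in an SR mode and a PE mode."""

    pair_id: str
    sample: str
    sr_key: str | None  # sequence-level row key, None if un-/ambiguously called
    pe_joined: bool
    pe_key: str | None


@dataclass
class FilterResult:
    filtered: pd.DataFrame
    flagged_rows: set[str]
    removed: pd.DataFrame  # same shape as sr matrix, removed counts
    class_report: pd.DataFrame  # per class: rows flagged, counts removed
    n_no_evidence: int  # SR-called pairs without a merged counterpart call


def flag_sr_false_positives(
    sr_matrix: pd.DataFrame,
    pe_matrix: pd.DataFrame,
    pair_trace: Iterable[PairTrace],
) -> FilterResult:
    """Remove SR counts contradicted by the merged-pair consensus call.

    A pair contributes evidence against its SR row when its merged read was
    called as a different row (canonical or another variant).  Unjoined or
    uncalled merged reads contribute nothing.  Idempotent: counts are
    clipped at zero.
    """
    removed = pd.DataFrame(0, index=sr_matrix.index, columns=sr_matrix.columns)
    n_no_evidence = 0
    for t in pair_trace:
        if t.sr_key is None:
            continue
        if not t.pe_joined or t.pe_key is None:
            n_no_evidence += 1
            continue
        if t.pe_key == t.sr_key:
            continue
        if t.sr_key in removed.index and t.sample in removed.columns:
            removed.loc[t.sr_key, t.sample] += 1
    removed = removed.clip(upper=sr_matrix)
    filtered = (sr_matrix - removed).clip(lower=0)
    flagged = set(removed.index[removed.sum(axis=1) > 0])
    rows = []
    for cls in sorted({class_of_key(k) for k in sr_matrix.index}):
        members = [k for k in sr_matrix.index if class_of_key(k) == cls]
        rows.append(
            {
                "class": cls,
                "rows_flagged": sum(1 for k in members if k in flagged),
                "counts_removed": int(removed.loc[members].to_numpy().sum()),
            }
        )
    report = pd.DataFrame(rows, columns=["class", "rows_flagged", "counts_removed"])
    return FilterResult(filtered, flagged, removed, report, n_no_evidence)


def log2fc_rank(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    min_samples: int = 10,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Rank rows by CPM-normalized log2 fold change between groups A and B.

    Rows with a positive count in fewer than ``min_samples`` samples are
    dropped.  Returns a descending-ordered Series (ties broken by row index),
    usable directly as a pre-ranked list for enrichment.
    """
    a_cols = [s for s, g in groups.items() if g == "A"]
    b_cols = [s for s, g in groups.items() if g == "B"]
    if not a_cols or not b_cols:
        raise MatrixError("both groups must contain at least one sample")
    missing = [s for s in (*a_cols, *b_cols) if s not in matrix.columns]
    if missing:
        raise MatrixError(f"samples not in matrix: {missing}")
    sub = matrix[a_cols + b_cols]
    keep = (sub > 0).sum(axis=1) >= min_samples
    lib = sub.sum(axis=0).replace(0, 1)
    cpm = sub / lib * 1e6
    cpm = cpm.loc[keep]
    metric = np.log2(cpm[a_cols].mean(axis=1) + pseudocount) - np.log2(
        cpm[b_cols].mean(axis=1) + pseudocount
    )
    order = sorted(metric.index, key=lambda k: (-metric[k], k))
    return metric.loc[order]


def write_rank_file(ranked: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in ranked.items():
            fh.write(f"{key}\t{value:.6g}\n")


def read_rank_file(path: str | Path) -> pd.Series:
    """Read an externally computed two-column (id, metric) rank file."""
    ids, metrics = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise MatrixError(f"{path}:{lineno}: expected 2 columns")
        ids.append(parts[0])
        metrics.append(float(parts[1]))
    s = pd.Series(metrics, index=ids)
    order = sorted(s.index, key=lambda k: (-s[k], k))
    return s.loc[order]


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
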