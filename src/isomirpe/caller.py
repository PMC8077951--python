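"""IsomiR calling: assign reads to mature miRNAs and miRTOP variant classes.

A processed read is explained against every anchored mature miRNA by
enumerating decompositions into a signed 5' shift, a signed 3' shift
(positive = templated extension drawn from the hairpin flank, negative =
trim), a short non-templated 3' tail, and up to ``max_snv`` internal
substitutions.  The decomposition with the fewest total edits wins; ties
within an anchor prefer fewer SNVs, then smaller terminal shifts, then a
shorter tail — terminal-length explanations are biologically and
technically more plausible than internal edits.  An equal best edit count
across two or more anchors is reported as ambiguous, and ambiguous reads
are excluded from expression matrices downstream.

SNVs are only placed on mature-aligned positions (never inside templated
extensions — a mismatched extension base is a non-templated addition), so
every SNV has a well-defined 1-based position on the canonical mature
sequence and falls into one of the miRTOP positional classes.

Unique sequences are named by reversible "license plate" identifiers in the
miRTOP envelope ``iso-<length>-<code>``; this implementation encodes the
sequence as a base-36 rendering of its base-4 value (A=0, C=1, G=2, T=3),
zero-padded so that encoding is injective per length and exactly decodable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .reference import MatureAnchor
from .variants import (
    SNV_WINDOWS,
    ISO_SNV,
    CANONICAL,
)

CANONICAL_LABEL = "NA"  # miR.gff3 Variant attribute for the reference form


@dataclass(frozen=True)
class CallLimits:
    max_shift: int = 3
    max_add: int = 3
    max_snv: int = 1
    min_len: int = 16
    max_len: int = 28


@dataclass(frozen=True)
class Decomposition:
    """One way of explaining a read against an anchor."""

    shift5: int
    shift3: int
    added: str
    snvs: tuple[tuple[int, str, str], ...]  # (1-based mature pos, ref, alt)

    @property
    def n_edits(self) -> int:
        return (
            abs(self.shift5) + abs(self.shift3) + len(self.added) + len(self.snvs)
        )

    @property
    def is_canonical(self) -> bool:
        return self.n_edits == 0


@dataclass(frozen=True)
class IsomiRCall:
    sequence: str
    mirna: str
    hairpin: str
    variant_label: str
    uid: str
    decomposition: Decomposition
    start: int  # 0-based half-open span on the hairpin
    end: int

    @property
    def n_edits(self) -> int:
        return self.decomposition.n_edits

    @property
    def variant_class(self) -> str:
        return class_of_label(self.variant_label)


@dataclass(frozen=True)
class CallResult:
    status: str  # "assigned" | "ambiguous" | "unassigned"
    call: IsomiRCall | None = None


def classify_snv_position(pos: int, mature_len: int = 22) -> str:
    """miRTOP positional class of a substitution at 1-based ``pos``."""
    if not 1 <= pos <= mature_len:
        raise ValueError(f"position {pos} outside mature of length {mature_len}")
    for label, (lo, hi) in SNV_WINDOWS.items():
        if lo <= pos <= hi:
            return label
    return ISO_SNV


def variant_label(decomp: Decomposition, mature_len: int) -> str:
    """miRTOP-style label, comma-joined for compound (mixed) variants."""
    if decomp.is_canonical:
        return CANONICAL_LABEL
    parts = []
    if decomp.shift5:
        parts.append(f"iso_5p:{decomp.shift5:+d}")
    if decomp.shift3:
        parts.append(f"iso_3p:{decomp.shift3:+d}")
    if decomp.added:
        parts.append(f"iso_add3p:{len(decomp.added)}")
    for pos, _ref, _alt in decomp.snvs:
        parts.append(classify_snv_position(pos, mature_len))
    return ",".join(parts)


def class_of_label(label: str) -> str:
    """Collapse a variant label to its isomiR class ('mixed' if compound)."""
    if label == CANONICAL_LABEL:
        return CANONICAL
    if "," in label:
        return "mixed"
    return label.split(":")[0]


# ---------------------------------------------------------------------------
# license plates

_B36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_BASE_ORD = {"A": 0, "C": 1, "G": 2, "T": 3}
_ORD_BASE = "ACGT"


def _b36_width(length: int) -> int:
    value, width = 4**length - 1, 1
    while value >= 36:
        value //= 36
        width += 1
    return width


def license_plate(seq: str) -> str:
    """Encode a sequence as ``iso-<len>-<code>`` (reversible, injective)."""
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    value = 0
    for base in seq:
        if base not in _BASE_ORD:
            raise ValueError(f"invalid base {base!r} in sequence")
        value = value * 4 + _BASE_ORD[base]
    digits = []
    while value:
        value, rem = divmod(value, 36)
        digits.append(_B36[rem])
    code = "".join(reversed(digits)).rjust(_b36_width(len(seq)), "0")
    return f"iso-{len(seq)}-{code}"


def decode_license_plate(uid: str) -> str:
    parts = uid.split("-")
    if len(parts) != 3 or parts[0] != "iso":
        raise ValueError(f"malformed UID {uid!r}")
    try:
        length = int(parts[1])
        value = int(parts[2], 36)
    except ValueError as exc:
        raise ValueError(f"malformed UID {uid!r}") from exc
    if length < 1 or value >= 4**length:
        raise ValueError(f"UID {uid!r} inconsistent with its length field")
    bases = []
    for _ in range(length):
        value, rem = divmod(value, 4)
        bases.append(_ORD_BASE[rem])
    return "".join(reversed(bases))


# ---------------------------------------------------------------------------
# calling

class AnchorIndex:
    """k-mer prefilter mapping reads to candidate anchors.

    Indexes every k-mer of each flank-extended mature window; a read within
    the caller's limits (shifts <= 3, <= 1 SNV) always shares at least one
    exact k-mer with its true anchor's window for k <= 7 at min_len 16.
    """

    def __init__(self, anchors: Sequence[MatureAnchor], k: int = 7):
        self.anchors = list(anchors)
        self.k = k
        self._index: dict[str, set[int]] = {}
        for i, a in enumerate(self.anchors):
            window = a.flank5 + a.mature_seq + a.flank3
            for j in range(len(window) - k + 1):
                self._index.setdefault(window[j : j + k], set()).add(i)

    def candidates(self, seq: str) -> list[MatureAnchor]:
        hits: set[int] = set()
        for j in range(len(seq) - self.k + 1):
            hits |= self._index.get(seq[j : j + self.k], set())
        return [self.anchors[i] for i in sorted(hits)]


def _decompose_against(
    seq: str, anchor: MatureAnchor, limits: CallLimits
) -> tuple[tuple, Decomposition] | None:
    """Best decomposition of ``seq`` against one anchor, or None.

    Returns (tie-break key, decomposition); the key orders by total edits,
    then SNV count, then terminal shift magnitude, then tail length, then
    (shift5, shift3) for determinism.
    """
    mature = anchor.mature_seq
    M, L = len(mature), len(seq)
    delta = L - M
    best: tuple[tuple, Decomposition] | None = None
    for s5 in range(-limits.max_shift, limits.max_shift + 1):
        if s5 > len(anchor.flank5) or -s5 >= M:
            continue
        ext5, trim5 = max(0, s5), max(0, -s5)
        for s3 in range(-limits.max_shift, limits.max_shift + 1):
            n_add = delta - s5 - s3
            if not 0 <= n_add <= limits.max_add:
                continue
            if s3 > len(anchor.flank3) or -s3 >= M:
                continue
            ext3, trim3 = max(0, s3), max(0, -s3)
            core_len = M + s5 + s3
            if core_len < 1 or trim5 + trim3 >= M:
                continue
            expected = (
                (anchor.flank5[len(anchor.flank5) - s5 :] if s5 > 0 else "")
                + mature[trim5 : M - trim3]
                + (anchor.flank3[:s3] if s3 > 0 else "")
            )
            core = seq[:core_len]
            snvs: list[tuple[int, str, str]] = []
            if core != expected:
                ok = True
                for i, (got, exp) in enumerate(zip(core, expected)):
                    if got == exp:
                        continue
                    if i < ext5 or i >= core_len - ext3:
                        ok = False  # no edits inside templated extensions
                        break
                    pos = i - ext5 + trim5 + 1  # 1-based on mature
                    snvs.append((pos, exp, got))
                    if len(snvs) > limits.max_snv:
                        ok = False
                        break
                if not ok:
                    continue
            added = seq[core_len:]
            if added:
                # a tail starting with the templated continuation base is a
                # (longer) templated extension, not an addition
                if trim3 > 0:
                    templated_next = mature[M - trim3]
                elif s3 < len(anchor.flank3):
                    templated_next = anchor.flank3[s3]
                else:
                    templated_next = None
                if templated_next is not None and added[0] == templated_next:
                    continue
            decomp = Decomposition(s5, s3, added, tuple(snvs))
            key = (
                decomp.n_edits,
                len(snvs),
                abs(s5) + abs(s3),
                n_add,
                s5,
                s3,
            )
            if best is None or key < best[0]:
                best = (key, decomp)
    return best


def call_isomir(
    seq: str,
    anchors: Sequence[MatureAnchor] | AnchorIndex,
    limits: CallLimits = CallLimits(),
) -> CallResult:
    """Assign a read sequence to (miRNA, variant, UID), or declare it
    ambiguous / unassigned.

    ``anchors`` may be a prebuilt :class:`AnchorIndex` (recommended when
    calling many reads) or a plain anchor list.
    """
    if not limits.min_len <= len(seq) <= limits.max_len:
        return CallResult("unassigned")
    if isinstance(anchors, AnchorIndex):
        candidates = anchors.candidates(seq)
    else:
        candidates = list(anchors)
    per_anchor: list[tuple[tuple, Decomposition, MatureAnchor]] = []
    for anchor in candidates:
        hit = _decompose_against(seq, anchor, limits)
        if hit is not None:
            per_anchor.append((hit[0], hit[1], anchor))
    if not per_anchor:
        return CallResult("unassigned")
    best_edits = min(k[0][0] for k in per_anchor)
    top = [t for t in per_anchor if t[0][0] == best_edits]
    if len({t[2].mature_name for t in top}) > 1:
        return CallResult("ambiguous")
    key, decomp, anchor = min(top, key=lambda t: t[0])
    label = variant_label(decomp, len(anchor.mature_seq))
    call = IsomiRCall(
        sequence=seq,
        mirna=anchor.mature_name,
        hairpin=anchor.hairpin_name,
        variant_label=label,
        uid=license_plate(seq),
        decomposition=decomp,
        start=anchor.start - decomp.shift5,
        end=anchor.end + decomp.shift3 + len(decomp.added),
    )
    return CallResult("assigned", call)


# ---------------------------------------------------------------------------
# miR.gff3 (miRTOP dialect)

@dataclass(frozen=True)
class MirGff3Entry:
    hairpin: str
    feature_type: str
    start: int  # 1-based inclusive, as in the file
    end: int
    sequence: str
    uid: str
    name: str
    parent: str
    variant: str
    expression: tuple[int, ...]


_REQUIRED_ATTRS = ("Read", "UID", "Name", "Parent", "Variant", "Expression")


def write_mirgff3(
    calls_counts: Iterable[tuple[IsomiRCall, Sequence[int]]],
    samples: Sequence[str],
    path: str | Path,
) -> None:
    """Write calls with per-sample counts as a miRTOP-style miR.gff3 file."""
    with open(path, "w") as fh:
        fh.write("## mirGFF3. VERSION 1.2\n")
        fh.write("## source-ontology: isomirpe\n")
        fh.write(f"## COLDATA: {','.join(samples)}\n")
        for call, counts in calls_counts:
            if len(counts) != len(samples):
                raise ValueError(
                    f"{call.uid}: {len(counts)} counts for {len(samples)} samples"
                )
            ftype = "ref_miRNA" if call.variant_label == CANONICAL_LABEL else "isomiR"
            attrs = (
                f"Read={call.sequence}; UID={call.uid}; Name={call.mirna}; "
                f"Parent={call.hairpin}; Variant={call.variant_label}; "
                f"Expression={','.join(str(int(c)) for c in counts)}"
            )
            fh.write(
                f"{call.hairpin}\tisomirpe\t{ftype}\t{call.start + 1}\t"
                f"{call.end}\t.\t+\t.\t{attrs}\n"
            )


def read_mirgff3(path: str | Path) -> tuple[list[MirGff3Entry], list[str]]:
    """Parse a miR.gff3 file; returns (entries, sample names)."""
    entries: list[MirGff3Entry] = []
    samples: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("## COLDATA:"):
            samples = [s.strip() for s in line.split(":", 1)[1].split(",") if s.strip()]
            continue
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
        attrs: dict[str, str] = {}
        for chunk in cols[8].split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            if "=" not in chunk:
                raise ValueError(f"{path}:{lineno}: malformed attribute {chunk!r}")
            key, value = chunk.split("=", 1)
            attrs[key.strip()] = value.strip()
        missing = [a for a in _REQUIRED_ATTRS if a not in attrs]
        if missing:
            raise ValueError(f"{path}:{lineno}: missing attributes {missing}")
        try:
            expression = tuple(int(x) for x in attrs["Expression"].split(","))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad Expression field") from exc
        entries.append(
            MirGff3Entry(
                hairpin=cols[0],
                feature_type=cols[2],
                start=int(cols[3]),
                end=int(cols[4]),
                sequence=attrs["Read"],
                uid=attrs["UID"],
                name=attrs["Name"],
                parent=attrs["Parent"],
                variant=attrs["Variant"],
                expression=expression,
            )
        )
    return entries, samples
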