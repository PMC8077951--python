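"""Mature/hairpin miRNA references and synthetic miRBase-like fixtures.

A mature miRNA is excised from a precursor hairpin (pre-miRNA); every isomiR
classification decision in this package is made in the coordinate frame of
the mature sequence anchored inside its hairpin, because length variants at
either terminus are called *templated* exactly when the extra bases match the
hairpin flanks.  This module reads miRBase-style FASTA, locates each mature
within its hairpin, and can generate synthetic references with the same
geometry for testing and simulation.

Coordinates are 0-based half-open throughout; 1-based coordinates appear only
in GFF3 serialization (see :mod:`isomirpe.caller`).  RNA alphabets are
normalized to DNA (U -> T) at ingestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGT")

#: bases of templated flank retained on each side of an anchor; equals the
#: largest 5'/3' shift the caller will consider (see caller.CallLimits).
DEFAULT_MAX_SHIFT = 3


class ReferenceError(ValueError):
    """Malformed reference input (FASTA syntax, duplicate names, alphabet)."""


class AnchorError(ValueError):
    """A mature sequence cannot be uniquely located inside a hairpin."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceError(f"empty sequence for record {self.name!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ReferenceError(
                f"record {self.name!r} has non-ACGT characters: {sorted(bad)}"
            )


@dataclass(frozen=True)
class MatureAnchor:
    """A mature miRNA located inside its hairpin.

    ``hairpin_seq[start:end] == mature_seq``; ``flank5``/``flank3`` are the
    templated bases immediately up/downstream of the mature in the hairpin,
    capped at ``max_shift`` nucleotides each.
    """

    mature_name: str
    hairpin_name: str
    start: int
    end: int
    mature_seq: str
    flank5: str
    flank3: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.mature_seq):
            raise AnchorError(
                f"{self.mature_name}: span {self.start}:{self.end} does not "
                f"match mature length {len(self.mature_seq)}"
            )


def normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (miRBase-style) FASTA file into :class:`SequenceRecord` list.

    U is normalized to T; record order is preserved; duplicate names raise.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        name = rec.id
        if name in seen:
            raise ReferenceError(f"duplicate record name {name!r} (entry {i + 1})")
        seen.add(name)
        records.append(SequenceRecord(name, normalize_sequence(str(rec.seq))))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = (
        _BioSeqRecord(Seq(r.sequence), id=r.name, description="") for r in records
    )
    SeqIO.write(bio, str(path), "fasta")


def read_name_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping mature name -> hairpin name."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ReferenceError(f"name map line {lineno}: expected 2 columns")
        mapping[parts[0]] = parts[1]
    return mapping


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def anchor_mature(
    mature: SequenceRecord,
    hairpins: Sequence[SequenceRecord],
    name_map: Mapping[str, str] | None = None,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> MatureAnchor:
    """Locate ``mature`` inside its hairpin and return the anchor.

    With ``name_map`` the designated hairpin is searched; otherwise the mature
    must occur in exactly one hairpin.  Multiple occurrences (within a hairpin
    or across hairpins) raise :class:`AnchorError` — miRBase families with a
    mature present in several hairpins are skipped upstream, not guessed at.
    """
    if name_map is not None:
        target = name_map.get(mature.name)
        if target is None:
            raise AnchorError(f"{mature.name}: not present in name map")
        candidates = [h for h in hairpins if h.name == target]
        if not candidates:
            raise AnchorError(f"{mature.name}: hairpin {target!r} not found")
    else:
        candidates = [h for h in hairpins if mature.sequence in h.sequence]
        if not candidates:
            raise AnchorError(f"{mature.name}: not found in any hairpin")
        if len(candidates) > 1:
            raise AnchorError(
                f"{mature.name}: occurs in {len(candidates)} hairpins "
                f"({', '.join(h.name for h in candidates)})"
            )
    hairpin = candidates[0]
    hits = _find_all(hairpin.sequence, mature.sequence)
    if not hits:
        raise AnchorError(f"{mature.name}: not found in hairpin {hairpin.name}")
    if len(hits) > 1:
        raise AnchorError(
            f"{mature.name}: occurs {len(hits)} times in hairpin "
            f"{hairpin.name} (offsets {hits})"
        )
    start = hits[0]
    end = start + len(mature.sequence)
    return MatureAnchor(
        mature_name=mature.name,
        hairpin_name=hairpin.name,
        start=start,
        end=end,
        mature_seq=mature.sequence,
        flank5=hairpin.sequence[max(0, start - max_shift) : start],
        flank3=hairpin.sequence[end : end + max_shift],
    )


def anchor_all(
    matures: Sequence[SequenceRecord],
    hairpins: Sequence[SequenceRecord],
    name_map: Mapping[str, str] | None = None,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> list[MatureAnchor]:
    """Anchor every mature, skipping ambiguous/unanchorable ones with a warning."""
    anchors = []
    for m in matures:
        try:
            anchors.append(anchor_mature(m, hairpins, name_map, max_shift))
        except AnchorError as exc:
            warnings.warn(f"skipping {m.name}: {exc}", stacklevel=2)
    return anchors


def make_synthetic_reference(
    n_mirnas: int,
    mature_len: int = 22,
    hairpin_len: int = 70,
    seed: int = 0,
    min_margin: int = 3,
) -> tuple[list[SequenceRecord], list[SequenceRecord], dict[str, str]]:
    """Generate a synthetic miRBase-like reference.

    Returns ``(hairpins, matures, name_map)``.  Each mature is embedded at a
    random offset of its hairpin leaving at least ``min_margin`` templated
    bases on both sides, and is guaranteed to occur exactly once in its
    hairpin (candidate hairpins with internal repeats of the mature are
    redrawn).  Deterministic for a fixed seed.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be positive")
    if hairpin_len < mature_len + 2 * min_margin:
        raise ValueError(
            f"hairpin_len ({hairpin_len}) must be >= mature_len + "
            f"{2 * min_margin} ({mature_len + 2 * min_margin})"
        )
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    hairpins: list[SequenceRecord] = []
    matures: list[SequenceRecord] = []
    name_map: dict[str, str] = {}
    for i in range(n_mirnas):
        while True:
            hp = b"".join(rng.choice(bases, size=hairpin_len)).decode()
            start = int(rng.integers(min_margin, hairpin_len - mature_len - min_margin + 1))
            mature = hp[start : start + mature_len]
            if hp.count(mature) == 1:
                break
        h_name = f"syn-mir-{i + 1}"
        m_name = f"syn-miR-{i + 1}"
        hairpins.append(SequenceRecord(h_name, hp))
        matures.append(SequenceRecord(m_name, mature))
        name_map[m_name] = h_name
    return hairpins, matures, name_map
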