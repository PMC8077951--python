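"""Ground-truth isomiR simulation ("biological variation").

For each selected miRNA one isoform per variant class is generated: the
canonical mature sequence, templated 5'/3' length variants (iso_5p/iso_3p),
a non-templated 3' addition (iso_add3p), and single-nucleotide variants in
each positional window of the miRTOP classification (seed 2-7, central
offset 8, central 9-12, central supplementary 13-17, and iso_snv for the
remaining positions).  Each non-canonical class is independently dropped
with probability ``p_drop``; random positive integer frequencies are then
allocated over the retained isoforms so that they sum exactly to
``per_mirna_total`` copies per miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import MatureAnchor

CANONICAL = "canonical"
ISO_5P = "iso_5p"
ISO_3P = "iso_3p"
ISO_ADD3P = "iso_add3p"
ISO_SNV_SEED = "iso_snv_seed"
ISO_SNV_CENTRAL_OFFSET = "iso_snv_central_offset"
ISO_SNV_CENTRAL = "iso_snv_central"
ISO_SNV_CENTRAL_SUPP = "iso_snv_central_supp"
ISO_SNV = "iso_snv"

SNV_CLASSES = (
    ISO_SNV_SEED,
    ISO_SNV_CENTRAL_OFFSET,
    ISO_SNV_CENTRAL,
    ISO_SNV_CENTRAL_SUPP,
    ISO_SNV,
)

VARIANT_TYPES = (CANONICAL, ISO_5P, ISO_3P, ISO_ADD3P) + SNV_CLASSES

#: 1-based positional windows on the mature sequence for SNV classes
#: (miRTOP convention; window upper bounds inclusive).
SNV_WINDOWS = {
    ISO_SNV_SEED: (2, 7),
    ISO_SNV_CENTRAL_OFFSET: (8, 8),
    ISO_SNV_CENTRAL: (9, 12),
    ISO_SNV_CENTRAL_SUPP: (13, 17),
}

_BASES = "ACGT"


class VariantError(ValueError):
    """Variant spec outside limits or infeasible for the given anchor."""


@dataclass(frozen=True)
class VariantSpec:
    """One variant mechanism applied to a canonical mature sequence.

    ``shift5``/``shift3`` are signed terminal length changes (positive =
    longer, drawn from the templated hairpin flank; negative = trimmed).
    ``added`` is a non-templated 3' tail whose first base differs from the
    templated flank continuation.  ``snv`` is (1-based mature position,
    ref base, alt base).  Exactly one mechanism is set for non-canonical
    specs; all are unset for canonical.
    """

    variant_type: str
    shift5: int = 0
    shift3: int = 0
    added: str = ""
    snv: tuple[int, str, str] | None = None

    def __post_init__(self) -> None:
        if self.variant_type not in VARIANT_TYPES:
            raise VariantError(f"unknown variant type {self.variant_type!r}")
        mechanisms = [
            self.shift5 != 0,
            self.shift3 != 0,
            self.added != "",
            self.snv is not None,
        ]
        if self.variant_type == CANONICAL:
            if any(mechanisms):
                raise VariantError("canonical spec must have no mechanism set")
        elif sum(mechanisms) != 1:
            raise VariantError(
                f"{self.variant_type}: exactly one mechanism must be set"
            )
        if self.snv is not None and self.snv[1] == self.snv[2]:
            raise VariantError("snv alt base equals ref base")


@dataclass(frozen=True)
class GroundTruthRecord:
    seq_id: str
    mirna: str
    spec: VariantSpec
    frequency: int
    sequence: str

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise VariantError(f"{self.seq_id}: frequency must be >= 1")


def apply_variant(anchor: MatureAnchor, spec: VariantSpec) -> str:
    """Realize ``spec`` against ``anchor`` and return the isoform sequence.

    Templated extensions draw from the hairpin flanks and raise
    :class:`VariantError` when the flank is too short; iso_add3p tails must
    not start with the templated flank base (otherwise they would be an
    iso_3p length variant, not an addition).
    """
    mature = anchor.mature_seq
    if spec.variant_type == CANONICAL:
        return mature
    if spec.shift5:
        if spec.shift5 > 0:
            if spec.shift5 > len(anchor.flank5):
                raise VariantError(
                    f"iso_5p:+{spec.shift5} exceeds 5' flank "
                    f"({len(anchor.flank5)} nt) of {anchor.mature_name}"
                )
            return anchor.flank5[len(anchor.flank5) - spec.shift5 :] + mature
        if -spec.shift5 >= len(mature):
            raise VariantError("iso_5p trim removes entire mature")
        return mature[-spec.shift5 :]
    if spec.shift3:
        if spec.shift3 > 0:
            if spec.shift3 > len(anchor.flank3):
                raise VariantError(
                    f"iso_3p:+{spec.shift3} exceeds 3' flank "
                    f"({len(anchor.flank3)} nt) of {anchor.mature_name}"
                )
            return mature + anchor.flank3[: spec.shift3]
        if -spec.shift3 >= len(mature):
            raise VariantError("iso_3p trim removes entire mature")
        return mature[: spec.shift3]
    if spec.added:
        if anchor.flank3 and spec.added[0] == anchor.flank3[0]:
            raise VariantError(
                f"added tail {spec.added!r} starts with the templated flank "
                f"base {anchor.flank3[0]!r}: that is iso_3p, not iso_add3p"
            )
        return mature + spec.added
    pos, ref, alt = spec.snv  # type: ignore[misc]
    if not (1 <= pos <= len(mature)):
        raise VariantError(f"snv position {pos} outside mature (len {len(mature)})")
    if mature[pos - 1] != ref:
        raise VariantError(
            f"snv ref {ref!r} does not match mature base {mature[pos - 1]!r} "
            f"at position {pos}"
        )
    return mature[: pos - 1] + alt + mature[pos:]


def snv_positions_for_class(variant_type: str, mature_len: int) -> list[int]:
    """1-based mature positions eligible for an SNV of the given class."""
    if variant_type in SNV_WINDOWS:
        lo, hi = SNV_WINDOWS[variant_type]
        return [p for p in range(lo, hi + 1) if p <= mature_len]
    if variant_type == ISO_SNV:
        windowed = {
            p for lo, hi in SNV_WINDOWS.values() for p in range(lo, hi + 1)
        }
        return [p for p in range(1, mature_len + 1) if p not in windowed]
    raise VariantError(f"{variant_type!r} is not an SNV class")


def _sample_spec(
    anchor: MatureAnchor,
    variant_type: str,
    rng: np.random.Generator,
    max_shift: int,
    max_add: int,
) -> VariantSpec | None:
    """Draw one feasible spec of ``variant_type``, or None if infeasible."""
    mature = anchor.mature_seq
    if variant_type == ISO_5P or variant_type == ISO_3P:
        flank = anchor.flank5 if variant_type == ISO_5P else anchor.flank3
        pos_max = min(max_shift, len(flank))
        shifts = [s for s in range(-max_shift, pos_max + 1) if s != 0]
        if not shifts:
            return None
        shift = int(rng.choice(shifts))
        key = "shift5" if variant_type == ISO_5P else "shift3"
        return VariantSpec(variant_type, **{key: shift})
    if variant_type == ISO_ADD3P:
        n = int(rng.integers(1, max_add + 1))
        forbidden = anchor.flank3[0] if anchor.flank3 else None
        first_choices = [b for b in _BASES if b != forbidden]
        tail = str(rng.choice(first_choices)) + "".join(
            rng.choice(list(_BASES), size=n - 1)
        )
        return VariantSpec(variant_type, added=tail)
    positions = snv_positions_for_class(variant_type, len(mature))
    if not positions:
        return None
    pos = int(rng.choice(positions))
    ref = mature[pos - 1]
    alt = str(rng.choice([b for b in _BASES if b != ref]))
    return VariantSpec(variant_type, snv=(pos, ref, alt))


def _allocate_frequencies(
    n_cells: int, total: int, rng: np.random.Generator
) -> np.ndarray:
    """Random positive integer frequencies over ``n_cells`` summing to ``total``.

    Symmetric multinomial draw; zero cells are repaired by transferring one
    count from the largest cell, preserving the exact total.
    """
    if n_cells > total:
        raise VariantError(f"cannot give {n_cells} isoforms positive counts of {total}")
    freqs = rng.multinomial(total, np.full(n_cells, 1.0 / n_cells))
    while (freqs == 0).any():
        freqs[int(np.argmax(freqs == 0))] += 1
        freqs[int(np.argmax(freqs))] -= 1
    return freqs


def build_truth_set(
    anchors: list[MatureAnchor],
    n_mirnas: int = 100,
    per_mirna_total: int = 100,
    seed: int = 0,
    p_drop: float = 0.2,
    max_shift: int = 3,
    max_add: int = 3,
) -> list[GroundTruthRecord]:
    """Build the ground-truth isoform population.

    Selects ``n_mirnas`` anchors uniformly at random; per miRNA keeps the
    canonical plus one isoform per surviving variant class (each class
    independently dropped with probability ``p_drop``), all sequences
    distinct, with positive integer frequencies summing to
    ``per_mirna_total``.  Deterministic for a fixed seed.
    """
    if len(anchors) < n_mirnas:
        raise VariantError(
            f"need at least {n_mirnas} anchors, have {len(anchors)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(anchors), size=n_mirnas, replace=False)
    records: list[GroundTruthRecord] = []
    for idx in chosen:
        anchor = anchors[int(idx)]
        isoforms: list[tuple[VariantSpec, str]] = [
            (VariantSpec(CANONICAL), anchor.mature_seq)
        ]
        seqs = {anchor.mature_seq}
        for vt in VARIANT_TYPES[1:]:
            if rng.random() < p_drop:
                continue
            spec_seq = None
            for _ in range(20):  # resample on (rare) sequence collisions
                spec = _sample_spec(anchor, vt, rng, max_shift, max_add)
                if spec is None:
                    break
                seq = apply_variant(anchor, spec)
                if seq not in seqs:
                    spec_seq = (spec, seq)
                    break
            if spec_seq is None:
                continue
            seqs.add(spec_seq[1])
            isoforms.append(spec_seq)
        freqs = _allocate_frequencies(len(isoforms), per_mirna_total, rng)
        for k, ((spec, seq), freq) in enumerate(zip(isoforms, freqs)):
            records.append(
                GroundTruthRecord(
                    seq_id=f"{anchor.mature_name}.{k}",
                    mirna=anchor.mature_name,
                    spec=spec,
                    frequency=int(freq),
                    sequence=seq,
                )
            )
    return records


_TRUTH_COLUMNS = [
    "seq_id",
    "mirna",
    "variant_type",
    "shift5",
    "shift3",
    "added",
    "snv_pos",
    "snv_ref",
    "snv_alt",
    "frequency",
    "sequence",
]


def truth_to_frame(records: list[GroundTruthRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        snv = r.spec.snv or (0, "", "")
        rows.append(
            (
                r.seq_id,
                r.mirna,
                r.spec.variant_type,
                r.spec.shift5,
                r.spec.shift3,
                r.spec.added,
                snv[0],
                snv[1],
                snv[2],
                r.frequency,
                r.sequence,
            )
        )
    return pd.DataFrame(rows, columns=_TRUTH_COLUMNS)


def write_truth(records: list[GroundTruthRecord], path: str | Path) -> None:
    truth_to_frame(records).to_csv(path, index=False)


def read_truth(path: str | Path) -> list[GroundTruthRecord]:
    df = pd.read_csv(
        path,
        dtype={
            "added": "string",
            "snv_ref": "string",
            "snv_alt": "string",
            "frequency": "int64",
            "snv_pos": "int64",
        },
        keep_default_na=False,
    )
    if list(df.columns) != _TRUTH_COLUMNS:
        raise VariantError(
            f"truth table schema mismatch: got columns {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        snv = (
            (int(row.snv_pos), str(row.snv_ref), str(row.snv_alt))
            if int(row.snv_pos) > 0
            else None
        )
        spec = VariantSpec(
            variant_type=row.variant_type,
            shift5=int(row.shift5),
            shift3=int(row.shift3),
            added=str(row.added),
            snv=snv,
        )
        records.append(
            GroundTruthRecord(
                seq_id=row.seq_id,
                mirna=row.mirna,
                spec=spec,
                frequency=int(row.frequency),
                sequence=row.sequence,
            )
        )
    return records
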