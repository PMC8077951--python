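"""Technical read simulation: 2x50 nt paired reads with adapter read-through.

Small-RNA inserts (16-28 nt) are shorter than the read length, so both mates
read through the insert into adapter sequence: R1 sees the insert followed by
the 3' adapter, R2 sees the reverse-complemented insert followed by the
reverse complement of the 5' adapter.  Substitution errors are injected per
cycle from a parametric profile; an Illumina-like profile elevates error
rates over the first cycles and towards the end of the read, with R2 twice as
error-prone as R1 at every cycle.  Indels are not modeled — at 50 nt Illumina
indel rates are orders of magnitude below substitution rates and the
downstream analysis concerns substitutions and termini.

Each fragment is assigned a random orientation with probability 0.5 and
reverse-complement-orientation fragments are discarded as whole pairs, so a
ground-truth isoform with frequency f at coverage c yields Binomial(f*c, 0.5)
retained pairs (expected f*c/2) and the simulated frequency spectrum is
preserved up to binomial noise.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .variants import GroundTruthRecord

# TruSeq Small RNA kit adapters
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

# constant downstream construct sequence read after the adapter when the
# read length exceeds insert+adapter (content is irrelevant post-trimming)
_FILLER = "ATCTCGTATGCCGTCTTCTGCTTGAAAAAAAAAAAAAAAAAAAAAAAAAA"

_COMP = str.maketrans("ACGT", "TGCA")
_BASE2IDX = {b: i for i, b in enumerate("ACGT")}
_IDX2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorProfile:
    """Per-cycle substitution error rates and deterministic quality model."""

    read_len: int
    r1_rates: np.ndarray
    r2_rates: np.ndarray
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5

    def __post_init__(self) -> None:
        for name, rates in (("r1", self.r1_rates), ("r2", self.r2_rates)):
            if len(rates) != self.read_len:
                raise SimulationError(f"{name}_rates length != read_len")
            if ((rates < 0) | (rates >= 1)).any():
                raise SimulationError(f"{name}_rates must lie in [0, 1)")

    def qual_string(self, which: str) -> str:
        """Phred+33 quality string implied by the rates (Q = -10 log10 rate)."""
        rates = self.r1_rates if which == "r1" else self.r2_rates
        quals = [
            min(41, int(round(-10 * math.log10(r)))) if r > 0 else 41
            for r in rates
        ]
        return "".join(chr(33 + max(2, q)) for q in quals)


def default_profile(
    kind: str = "hiseq-like",
    read_len: int = 50,
    epsilon: float = 0.001,
    baseline: float = 0.001,
    end_rate: float = 0.004,
    early_factor: float = 3.0,
    early_cycles: int = 4,
    r2_factor: float = 2.0,
    **adapters: str,
) -> ErrorProfile:
    """Build a named error profile.

    ``hiseq-like``: R1 at ``baseline`` mid-read rising linearly over the last
    half to ``end_rate`` at the final cycle, with the first ``early_cycles``
    cycles elevated by ``early_factor`` (base-caller calibration dip); R2 is
    ``r2_factor`` times R1 at every cycle.  ``uniform``: flat ``epsilon`` on
    both reads (``epsilon=0`` gives error-free reads).
    """
    if kind == "uniform":
        rates = np.full(read_len, float(epsilon))
        return ErrorProfile(read_len, rates, rates.copy(), **adapters)
    if kind != "hiseq-like":
        raise SimulationError(f"unknown profile kind {kind!r}")
    cycles = np.arange(read_len)
    half = read_len // 2
    ramp = np.clip((cycles - half) / max(1, read_len - 1 - half), 0.0, 1.0)
    r1 = baseline + (end_rate - baseline) * ramp
    r1[:early_cycles] *= early_factor
    r2 = np.minimum(r2_factor * r1, 0.999)
    return ErrorProfile(read_len, r1, r2, **adapters)


@dataclass(frozen=True)
class FastqRead:
    name: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise SimulationError(
                f"{self.name}: sequence/quality length mismatch"
            )


@dataclass(frozen=True)
class OrientationEntry:
    pair_id: str
    truth_id: str
    kept: bool


def _template(insert: str, adapter: str, read_len: int) -> np.ndarray:
    full = (insert + adapter + _FILLER)[:read_len]
    return np.frombuffer(full.encode(), dtype=np.uint8).copy()


def _inject_errors(
    reads: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> None:
    """Substitute bases in-place with per-cycle probabilities ``rates``."""
    if reads.size == 0 or not rates.any():
        return
    mask = rng.random(reads.shape) < rates[None, :]
    n = int(mask.sum())
    if n == 0:
        return
    lut = np.zeros(256, dtype=np.uint8)
    for b, i in _BASE2IDX.items():
        lut[ord(b)] = i
    orig = lut[reads[mask]]
    shifted = (orig + rng.integers(1, 4, size=n)) % 4
    reads[mask] = _IDX2BASE[shifted]


def simulate_reads(
    truth: Sequence[GroundTruthRecord],
    profile: ErrorProfile,
    coverage: int = 10,
    seed: int = 0,
    discard_rc: bool = True,
) -> tuple[list[FastqRead], list[FastqRead], list[OrientationEntry]]:
    """Simulate paired reads for a ground-truth population.

    Each record contributes ``frequency * coverage`` fragments; with
    ``discard_rc`` each fragment is kept with probability 0.5 (the pair of a
    reverse-complement-orientation fragment is discarded with it).  Returns
    (R1 reads, R2 reads, orientation log).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    read_len = profile.read_len
    for rec in truth:
        if len(rec.sequence) >= read_len:
            raise SimulationError(
                f"{rec.seq_id}: insert length {len(rec.sequence)} must be "
                f"shorter than read length {read_len} (adapter read-through)"
            )
    if not truth:
        return [], [], []

    counts = np.array([rec.frequency * coverage for rec in truth])
    rec_idx = np.repeat(np.arange(len(truth)), counts)
    total = int(counts.sum())
    kept = (
        rng.random(total) < 0.5 if discard_rc else np.ones(total, dtype=bool)
    )

    log = [
        OrientationEntry(f"frag{i}", truth[int(rec_idx[i])].seq_id, bool(kept[i]))
        for i in range(total)
    ]

    r1_templates = np.stack(
        [_template(rec.sequence, profile.adapter3, read_len) for rec in truth]
    )
    r2_templates = np.stack(
        [
            _template(revcomp(rec.sequence), revcomp(profile.adapter5), read_len)
            for rec in truth
        ]
    )
    kept_idx = rec_idx[kept]
    r1 = r1_templates[kept_idx]
    r2 = r2_templates[kept_idx]
    _inject_errors(r1, profile.r1_rates, rng)
    _inject_errors(r2, profile.r2_rates, rng)

    q1 = profile.qual_string("r1")
    q2 = profile.qual_string("r2")
    kept_ids = np.flatnonzero(kept)
    reads1 = [
        FastqRead(f"frag{int(i)}", r1[k].tobytes().decode(), q1)
        for k, i in enumerate(kept_ids)
    ]
    reads2 = [
        FastqRead(f"frag{int(i)}", r2[k].tobytes().decode(), q2)
        for k, i in enumerate(kept_ids)
    ]
    return reads1, reads2, log


def _open(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with _open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[FastqRead]:
    reads = []
    with _open(path, "r") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 == 1 and lines[-1] == "":
        lines = lines[:-1]
    if len(lines) % 4 != 0:
        raise SimulationError(f"{path}: truncated FASTQ ({len(lines)} lines)")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise SimulationError(f"{path}: malformed record {i // 4}")
        if len(seq) != len(qual):
            raise SimulationError(
                f"{path}: record {i // 4}: sequence/quality length mismatch"
            )
        reads.append(FastqRead(header[1:].split()[0], seq, qual))
    return reads


def write_orientation_log(
    log: Iterable[OrientationEntry], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id,truth_id,kept\n")
        for e in log:
            fh.write(f"{e.pair_id},{e.truth_id},{int(e.kept)}\n")
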