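"""Benchmarking observed isomiR counts against simulated ground truth.

Each ground-truth isoform has an expected count (its simulated frequency
times an expected per-copy read yield).  Per truth item the observation is a
true positive when it matches the expectation within a symmetric relative
tolerance, a false positive when it exceeds it, and a false negative when it
falls short (including absence); observed (miRNA, variant class, sequence)
keys absent from the truth are "new generation" isomiRs and, by default,
also count against precision as wrongly assigned mass.  Sensitivity is
TP/(TP+FN) and precision TP/(TP+FP).  A true negative is defined as a truth
item with zero expectation and zero observation; since the simulator assigns
every isoform a positive frequency this is normally zero.

With orientation discarding the per-copy yield is binomial (mean coverage/2)
so exact matching is impossible; the default tolerance of 0.2 accommodates
the binomial spread, and tolerance 0 recovers strict count matching for
deterministic (no-discard, error-free) runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .variants import GroundTruthRecord

ObservedKey = tuple[str, str, str]  # (mirna, variant class, sequence)


@dataclass
class EvalMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    new_generation: int = 0

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None


def evaluate_calls(
    observed: Mapping[ObservedKey, int],
    truth: Sequence[GroundTruthRecord],
    expected_factor: float,
    tolerance: float = 0.2,
    fp_includes_new: bool = True,
) -> tuple[EvalMetrics, dict[str, EvalMetrics]]:
    """Score observed counts against the truth set.

    Returns (overall metrics, per-variant-class metrics).  ``observed`` maps
    (miRNA, variant class, sequence) to a count; ``expected_factor`` is the
    expected reads per truth copy (e.g. coverage * 0.5 under orientation
    discarding).
    """
    for key, count in observed.items():
        if count < 0:
            raise ValueError(f"negative observed count for {key}")
    overall = EvalMetrics()
    per_class: dict[str, EvalMetrics] = {}

    def cls_metrics(cls: str) -> EvalMetrics:
        return per_class.setdefault(cls, EvalMetrics())

    truth_keys: set[ObservedKey] = set()
    for rec in truth:
        key = (rec.mirna, rec.spec.variant_type, rec.sequence)
        truth_keys.add(key)
        expected = rec.frequency * expected_factor
        obs = observed.get(key, 0)
        m = cls_metrics(rec.spec.variant_type)
        if expected == 0:
            bucket = "tn" if obs == 0 else "fp"
        elif abs(obs - expected) <= tolerance * expected:
            bucket = "tp"
        elif obs > (1 + tolerance) * expected:
            bucket = "fp"
        else:
            bucket = "fn"
        setattr(overall, bucket, getattr(overall, bucket) + 1)
        setattr(m, bucket, getattr(m, bucket) + 1)

    for key in observed:
        if key not in truth_keys:
            overall.new_generation += 1
            cls_metrics(key[1]).new_generation += 1
    if fp_includes_new:
        overall.fp += overall.new_generation
        for m in per_class.values():
            m.fp += m.new_generation
    return overall, per_class


def metrics_frame(
    per_mode: Mapping[str, tuple[EvalMetrics, dict[str, EvalMetrics]]],
) -> pd.DataFrame:
    """Tabulate metrics as mode x class rows (class 'all' = overall)."""
    rows = []
    for mode, (overall, per_class) in per_mode.items():
        for cls, m in [("all", overall), *sorted(per_class.items())]:
            rows.append(
                {
                    "mode": mode,
                    "class": cls,
                    "TP": m.tp,
                    "FP": m.fp,
                    "FN": m.fn,
                    "TN": m.tn,
                    "new_generation": m.new_generation,
                    "sensitivity": m.sensitivity,
                    "precision": m.precision,
                }
            )
    return pd.DataFrame(rows)
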