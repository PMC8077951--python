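"""Pre-ranked set enrichment over isomiR classes.

Rows of the expression matrix, ranked by a log2 fold-change metric, are
tested for enrichment of each isomiR class using the weighted
Kolmogorov-Smirnov running statistic: walking down the ranked list, hits
(set members) increment the running sum by |metric|^p normalized over the
set, misses decrement by 1/(N - N_hits); the enrichment score (ES) is the
signed maximum-magnitude excursion.  Significance is assessed against a
set-label permutation null (random size-matched sets — the appropriate null
for a pre-ranked list, where no phenotype labels exist), the normalized ES
(NES) divides by the mean same-sign null magnitude, and FDR q-values follow
the standard pooled-null procedure across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import class_of_key, parse_row_key


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    nominal_p: float
    fdr_q: float


def build_class_sets(index: Sequence[str]) -> dict[str, set[str]]:
    """Group sequence-level row ids into one set per isomiR class.

    Each id belongs to exactly one class (compound labels go to 'mixed'),
    so the sets partition the index.
    """
    sets: dict[str, set[str]] = {}
    for key in index:
        parse_row_key(key)  # raises on unparseable ids
        sets.setdefault(class_of_key(key), set()).add(key)
    return sets


def _running_sum(
    metrics: np.ndarray, hit_mask: np.ndarray, p: float
) -> np.ndarray:
    n = len(metrics)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise EnrichmentError(
            "set must intersect the ranked list without covering it"
        )
    weights = np.abs(metrics, dtype=float) ** p
    hit_total = weights[hit_mask].sum()
    steps = np.full(n, -1.0 / (n - n_hit))
    if hit_total > 0:
        steps[hit_mask] = weights[hit_mask] / hit_total
    else:  # degenerate all-zero metrics: fall back to unweighted hits
        steps[hit_mask] = 1.0 / n_hit
    return np.cumsum(steps)


def enrichment_score(
    ranked: pd.Series, gene_set: set[str], p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score of ``gene_set`` on a ranked list.

    Returns (ES, running sum).  ES is the running-sum value of largest
    magnitude (sign preserved; earliest position on ties).
    """
    hit_mask = np.array([key in gene_set for key in ranked.index])
    running = _running_sum(ranked.to_numpy(), hit_mask, p)
    es = float(running[int(np.argmax(np.abs(running)))])
    return es, running


def _null_es(
    metrics: np.ndarray, n_hit: int, p: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES values for ``n_perm`` random size-matched sets (vectorized)."""
    n = len(metrics)
    weights = np.abs(metrics, dtype=float) ** p
    miss = 1.0 / (n - n_hit)
    # sorted hit positions per permutation
    pos = np.empty((n_perm, n_hit), dtype=np.int64)
    for i in range(n_perm):
        pos[i] = np.sort(rng.choice(n, size=n_hit, replace=False))
    w = weights[pos]
    totals = w.sum(axis=1, keepdims=True)
    unweighted = np.broadcast_to(1.0 / n_hit, w.shape)
    w = np.where(totals > 0, w / np.where(totals > 0, totals, 1.0), unweighted)
    cum = np.cumsum(w, axis=1)
    ranks = np.arange(1, n_hit + 1)
    # running-sum value at each hit (peak) and just before it (trough);
    # between hits the sum decays linearly, so extremes occur only there
    at_hit = cum - (pos + 1 - ranks) * miss
    before_hit = cum - w - (pos - (ranks - 1)) * miss
    candidates = np.concatenate([at_hit, before_hit], axis=1)
    idx = np.argmax(np.abs(candidates), axis=1)
    return candidates[np.arange(n_perm), idx]


def preranked_gsea(
    ranked: pd.Series,
    sets: Mapping[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    p: float = 1.0,
) -> list[EnrichmentResult]:
    """Run pre-ranked enrichment for every set; deterministic given seed."""
    if n_perm < 10:
        raise EnrichmentError("n_perm must be at least 10")
    rng = np.random.default_rng(seed)
    metrics = ranked.to_numpy()
    observed: list[tuple[str, int, float, np.ndarray]] = []
    for name in sorted(sets):
        members = sets[name] & set(ranked.index)
        if not members or len(members) == len(ranked):
            continue
        es, _ = enrichment_score(ranked, members, p)
        null = _null_es(metrics, len(members), p, n_perm, rng)
        observed.append((name, len(members), es, null))

    def _nes(es: float, null: np.ndarray) -> float:
        same = null[null >= 0] if es >= 0 else null[null < 0]
        denom = np.abs(same).mean() if same.size else np.abs(null).mean()
        return es / denom if denom > 0 else 0.0

    results_nes = [_nes(es, null) for _, _, es, null in observed]
    pooled = np.concatenate(
        [
            np.array([_nes(v, null) for v in null])
            for _, _, _, null in observed
        ]
    ) if observed else np.array([])

    results: list[EnrichmentResult] = []
    obs_nes = np.array(results_nes)
    for (name, size, es, null), nes in zip(observed, results_nes):
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size:
            nominal_p = float((np.abs(same) >= abs(es)).mean())
        else:
            nominal_p = 0.0
        same_pool = pooled[pooled >= 0] if nes >= 0 else pooled[pooled < 0]
        num = (
            float((np.abs(same_pool) >= abs(nes)).mean()) if same_pool.size else 0.0
        )
        same_obs = obs_nes[obs_nes >= 0] if nes >= 0 else obs_nes[obs_nes < 0]
        den = (
            float((np.abs(same_obs) >= abs(nes)).mean()) if same_obs.size else 0.0
        )
        fdr_q = min(1.0, num / den) if den > 0 else 1.0
        results.append(EnrichmentResult(name, size, es, nes, nominal_p, fdr_q))
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "Name": r.name,
                "Size": r.size,
                "ES": r.es,
                "NES": r.nes,
                "nominal_p": r.nominal_p,
                "FDR q-val": r.fdr_q,
            }
            for r in results
        ]
    )
    return df.sort_values("ES", ascending=False).reset_index(drop=True)


def write_gmt(sets: Mapping[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            ids = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tisomir_class\t{ids}\n")


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in open(path):
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            continue
        sets[parts[0]] = set(parts[2:])
    return sets
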