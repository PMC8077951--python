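"""End-to-end driver: simulate, preprocess, call, quantify, compare, enrich.

One experiment = one synthetic reference, one ground-truth isoform
population, and ``n_replicates`` independently simulated paired-read
samples, each analyzed in the four modes:

* ``SR1`` — trimmed forward reads;
* ``SR2`` — trimmed reverse reads, reverse-complemented;
* ``PE_0`` — merged pairs at 0% overlap mismatch tolerance;
* ``PE_8`` — merged pairs at 8% tolerance.

Downstream outputs are per-mode expression matrices, per-mode benchmarking
against the ground truth, the cross-mode comparison (unique sequences per
class, overlap partition), the single-read false-positive filter against the
merged-pair consensus, and pre-ranked enrichment of isomiR classes on the
SR-vs-PE fold-change ranking.  All randomness derives from one master seed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .caller import AnchorIndex, CallLimits, CallResult, call_isomir, write_mirgff3
from .enrichment import (
    EnrichmentResult,
    build_class_sets,
    preranked_gsea,
    results_frame,
    write_gmt,
)
from .evaluate import EvalMetrics, evaluate_calls, metrics_frame
from .preprocess import merge_pair, trim_adapter
from .quantify import (
    FilterResult,
    ModeComparison,
    PairTrace,
    compare_modes,
    flag_sr_false_positives,
    log2fc_rank,
    matrix_from_counts,
    parse_row_key,
    row_key,
    write_matrix,
    write_rank_file,
)
from .readsim import default_profile, revcomp, simulate_reads
from .reference import anchor_all, make_synthetic_reference, write_fasta
from .variants import SNV_CLASSES, build_truth_set, write_truth

logger = logging.getLogger(__name__)

PE_MODES = {"PE_0": 0.0, "PE_8": 0.08}


@dataclass
class RunConfig:
    """Full parameterization of one four-mode experiment."""

    seed: int = 1
    n_mirnas: int = 100
    n_reference: int | None = None  # synthetic reference size; default n_mirnas+20
    per_mirna_total: int = 100
    p_drop: float = 0.2
    mature_len: int = 22
    hairpin_len: int = 70
    coverage: int = 10
    profile_kind: str = "hiseq-like"
    profile_epsilon: float = 0.001  # only for the uniform profile
    discard_rc: bool = True
    n_replicates: int = 3
    trim_max_error: float = 0.10
    trim_min_overlap: int = 3
    quality_cutoff: int = 0
    merge_min_overlap: int = 6
    max_shift: int = 3
    max_add: int = 3
    max_snv: int = 1
    min_len: int = 16
    max_len: int = 28
    eval_tolerance: float = 0.2
    min_samples: int = 1
    n_perm: int = 1000
    weight_p: float = 1.0

    @property
    def limits(self) -> CallLimits:
        return CallLimits(
            self.max_shift, self.max_add, self.max_snv, self.min_len, self.max_len
        )

    @property
    def expected_factor(self) -> float:
        return self.coverage * (0.5 if self.discard_rc else 1.0)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ExperimentResult:
    config: RunConfig
    truth: list
    hairpins: list
    matures: list
    matrices: dict[str, pd.DataFrame]
    calls: dict[str, object]  # row key -> IsomiRCall
    evaluation: dict[str, dict[str, tuple[EvalMetrics, dict]]]
    comparison: ModeComparison
    fp_filter: FilterResult
    ranked: pd.Series
    enrichment: list[EnrichmentResult]
    attrition: pd.DataFrame
    seeds: dict[str, int]
    traces: list[PairTrace] = field(default_factory=list)

    def snv_family_unique_counts(self) -> dict[str, int]:
        """Unique sequences per mode whose (pure) class is an SNV class."""
        out = {}
        for mode, df in self.matrices.items():
            present = df.index[df.sum(axis=1) > 0]
            out[mode] = sum(
                1
                for k in present
                if parse_row_key(k)[1] in SNV_CLASSES
            )
        return out

    def mean_metric(self, mode: str, which: str) -> float:
        values = [
            getattr(overall, which)
            for overall, _ in self.evaluation[mode].values()
            if getattr(overall, which) is not None
        ]
        return float(np.mean(values)) if values else float("nan")


class _Caller:
    """Memoizing wrapper around call_isomir keyed by read sequence."""

    def __init__(self, index: AnchorIndex, limits: CallLimits):
        self.index = index
        self.limits = limits
        self.cache: dict[str, CallResult] = {}
        self.calls: dict[str, object] = {}  # row key -> IsomiRCall

    def key_of(self, seq: str) -> str | None:
        res = self.cache.get(seq)
        if res is None:
            res = call_isomir(seq, self.index, self.limits)
            self.cache[seq] = res
        if res.status != "assigned":
            return None
        key = row_key(res.call)
        self.calls.setdefault(key, res.call)
        return key

    def call_of(self, seq: str) -> CallResult:
        self.key_of(seq)
        return self.cache[seq]


def run_experiment(config: RunConfig) -> ExperimentResult:
    master = np.random.default_rng(config.seed)

    def child_seed() -> int:
        return int(master.integers(0, 2**31 - 1))

    seeds = {"reference": child_seed(), "truth": child_seed()}
    n_ref = config.n_reference or config.n_mirnas + 20
    hairpins, matures, name_map = make_synthetic_reference(
        n_ref, config.mature_len, config.hairpin_len, seeds["reference"]
    )
    anchors = anchor_all(matures, hairpins, name_map, config.max_shift)
    truth = build_truth_set(
        anchors,
        config.n_mirnas,
        config.per_mirna_total,
        seeds["truth"],
        config.p_drop,
        config.max_shift,
        config.max_add,
    )
    logger.info("truth set: %d isoforms over %d miRNAs", len(truth), config.n_mirnas)

    profile = default_profile(config.profile_kind, epsilon=config.profile_epsilon)
    adapter_r1 = profile.adapter3
    adapter_r2 = revcomp(profile.adapter5)
    caller = _Caller(AnchorIndex(anchors), config.limits)

    counts: dict[str, dict[str, Counter]] = {
        m: {} for m in ("SR1", "SR2", *PE_MODES)
    }
    observed: dict[str, dict[str, Counter]] = {
        m: {} for m in ("SR1", "SR2", *PE_MODES)
    }
    traces: list[PairTrace] = []
    attrition_rows = []

    for rep in range(1, config.n_replicates + 1):
        sample = f"rep{rep}"
        seeds[f"reads_{sample}"] = child_seed()
        reads1, reads2, olog = simulate_reads(
            truth, profile, config.coverage, seeds[f"reads_{sample}"], config.discard_rc
        )
        row = {
            "sample": sample,
            "fragments": len(olog),
            "pairs_kept": len(reads1),
        }
        for mode in counts:
            counts[mode][sample] = Counter()
            observed[mode][sample] = Counter()
        stats = {m: Counter() for m in counts}

        for r1, r2 in zip(reads1, reads2):
            t1 = trim_adapter(
                r1.sequence,
                r1.quality,
                adapter_r1,
                config.trim_max_error,
                config.trim_min_overlap,
                config.quality_cutoff,
            )
            t2 = trim_adapter(
                r2.sequence,
                r2.quality,
                adapter_r2,
                config.trim_max_error,
                config.trim_min_overlap,
                config.quality_cutoff,
            )
            mode_seqs = {
                "SR1": t1.sequence,
                "SR2": revcomp(t2.sequence),
            }
            tr1 = type(r1)(r1.name, t1.sequence, t1.quality)
            tr2 = type(r2)(r2.name, t2.sequence, t2.quality)
            pe_results = {}
            for mode, pct in PE_MODES.items():
                merged = merge_pair(tr1, tr2, config.merge_min_overlap, pct)
                pe_results[mode] = merged
                mode_seqs[mode] = merged.consensus_seq if merged.joined else None
                if merged.joined:
                    stats[mode]["joined"] += 1

            mode_keys = {}
            for mode, seq in mode_seqs.items():
                if seq is None:
                    mode_keys[mode] = None
                    continue
                res = caller.call_of(seq)
                stats[mode][res.status] += 1
                if res.status != "assigned":
                    mode_keys[mode] = None
                    continue
                key = row_key(res.call)
                mode_keys[mode] = key
                counts[mode][sample][key] += 1
                observed[mode][sample][
                    (res.call.mirna, res.call.variant_class, seq)
                ] += 1
            traces.append(
                PairTrace(
                    pair_id=f"{sample}:{r1.name}",
                    sample=sample,
                    sr_key=mode_keys["SR1"],
                    pe_joined=pe_results["PE_8"].joined,
                    pe_key=mode_keys["PE_8"],
                )
            )
        for mode in counts:
            row[f"{mode}_assigned"] = stats[mode]["assigned"]
            row[f"{mode}_unassigned"] = stats[mode]["unassigned"]
            row[f"{mode}_ambiguous"] = stats[mode]["ambiguous"]
            if mode in PE_MODES:
                row[f"{mode}_joined"] = stats[mode]["joined"]
        attrition_rows.append(row)
        logger.info(
            "%s: %d pairs, SR1 assigned %d, PE_0 joined %d",
            sample,
            len(reads1),
            stats["SR1"]["assigned"],
            stats["PE_0"]["joined"],
        )

    matrices = {
        mode: matrix_from_counts(
            {s: dict(c) for s, c in counts[mode].items()}
        )
        for mode in counts
    }
    evaluation = {
        mode: {
            sample: evaluate_calls(
                dict(observed[mode][sample]),
                truth,
                config.expected_factor,
                config.eval_tolerance,
            )
            for sample in observed[mode]
        }
        for mode in observed
    }
    comparison = compare_modes(matrices)
    fp_filter = flag_sr_false_positives(matrices["SR1"], matrices["PE_8"], traces)

    combined = pd.concat(
        [
            matrices["SR1"].rename(columns=lambda c: f"SR1_{c}"),
            matrices["PE_0"].rename(columns=lambda c: f"PE_0_{c}"),
        ],
        axis=1,
    ).fillna(0).astype(int)
    groups = {c: ("A" if c.startswith("SR1_") else "B") for c in combined.columns}
    ranked = log2fc_rank(combined, groups, config.min_samples)
    seeds["gsea"] = child_seed()
    sets = build_class_sets(list(ranked.index))
    enrichment = preranked_gsea(
        ranked, sets, config.n_perm, seeds["gsea"], config.weight_p
    )

    return ExperimentResult(
        config=config,
        truth=truth,
        hairpins=hairpins,
        matures=matures,
        matrices=matrices,
        calls=caller.calls,
        evaluation=evaluation,
        comparison=comparison,
        fp_filter=fp_filter,
        ranked=ranked,
        enrichment=enrichment,
        attrition=pd.DataFrame(attrition_rows),
        seeds=seeds,
        traces=traces,
    )


def write_outputs(result: ExperimentResult, outdir: str | Path) -> None:
    """Persist every artifact of an experiment plus a run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.hairpins, out / "hairpin.fa")
    write_fasta(result.matures, out / "mature.fa")
    write_truth(result.truth, out / "truth.csv")
    samples = list(result.matrices["SR1"].columns)
    for mode, matrix in result.matrices.items():
        write_matrix(matrix, out / f"matrix_{mode}.csv")
        calls_counts = [
            (result.calls[key], [int(x) for x in matrix.loc[key]])
            for key in matrix.index
            if key in result.calls
        ]
        write_mirgff3(calls_counts, samples, out / f"{mode}.gff3")
    metrics_frame(
        {m: ev[samples[0]] for m, ev in result.evaluation.items()}
    ).to_csv(out / "metrics_rep1.csv", index=False)
    rows = []
    for m, ev in result.evaluation.items():
        rows.append(
            {
                "mode": m,
                "mean_sensitivity": result.mean_metric(m, "sensitivity"),
                "mean_precision": result.mean_metric(m, "precision"),
            }
        )
    pd.DataFrame(rows).to_csv(out / "metrics_summary.csv", index=False)
    result.comparison.unique_counts.to_csv(out / "class_unique_counts.csv")
    venn_rows = [
        {"modes": "+".join(sorted(cell)), "n_sequences": n}
        for cell, n in sorted(
            result.comparison.venn.items(), key=lambda kv: "+".join(sorted(kv[0]))
        )
    ]
    pd.DataFrame(venn_rows).to_csv(out / "venn.csv", index=False)
    result.fp_filter.class_report.to_csv(out / "sr_fp_report.csv", index=False)
    write_matrix(result.fp_filter.filtered, out / "matrix_SR1_filtered.csv")
    write_rank_file(result.ranked, out / "sr1_vs_pe0.rnk")
    write_gmt(build_class_sets(list(result.ranked.index)), out / "class_sets.gmt")
    results_frame(result.enrichment).to_csv(out / "enrichment.csv", index=False)
    result.attrition.to_csv(out / "attrition.csv", index=False)
    manifest = {
        "isomirpe_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(result.config),
        "derived_seeds": result.seeds,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
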