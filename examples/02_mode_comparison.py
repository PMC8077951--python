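"""Compare the four analysis modes on error-bearing simulated reads.

Runs a small four-mode experiment under the Illumina-like error profile and
prints, per mode, the number of unique internal-SNV sequences and the mean
sensitivity/precision against the simulated truth.  Single-read modes
inflate SNV diversity (each sequencing error inside the insert mints a new
apparent isomiR); strict paired-end merging suppresses it.
"""

from isomirpe import RunConfig, run_experiment

result = run_experiment(RunConfig(seed=1, n_mirnas=30, n_replicates=2))
snv = result.snv_family_unique_counts()

print(f"{'mode':6s} {'unique SNV seqs':>16s} {'sensitivity':>12s} {'precision':>10s}")
for mode in ("SR2", "SR1", "PE_8", "PE_0"):
    print(
        f"{mode:6s} {snv[mode]:16d} "
        f"{result.mean_metric(mode, 'sensitivity'):12.3f} "
        f"{result.mean_metric(mode, 'precision'):10.3f}"
    )
print()
print("SNV-sequence diversity decreases monotonically from SR2 to PE_0;")
print("precision is highest in PE_0 because error reads fail the 0% merge.")
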