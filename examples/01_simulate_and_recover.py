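"""Parameter recovery on a noiseless synthetic cohort.

Simulates a small cohort with known per-gene kinetics (initiation rate,
termination fraction, promoter-proximal half-life), runs the full
estimation pipeline on the generated TT-seq / mNET-seq / ChIP-nexus
signals, and compares recovered values with the ground truth.
"""

import numpy as np

from polkinetics import AnalysisParams, SimConfig, run_cohort_pipeline, simulate_cohort

cohort = simulate_cohort(SimConfig(n_genes=60, noise="none", seed=42))
results = run_cohort_pipeline(
    cohort, AnalysisParams(antisense_min_coverage=0.0, seed=0)
)
truth = cohort.truth.df

print(f"genes with a major isoform: {len(results.models)}")
print(f"genes with stable pause sites: "
      f"{sum(s.stable for s in results.sites.values())}")

print("\ngene        class     I_0h (est/true)   t1/2 0h min (est/true)  "
      "termination 0h (est/true)")
table0 = results.decay[0]
for gid in table0.index[table0.status == "ok"][:6]:
    row = truth.loc[gid]
    est = table0.loc[gid]
    print(f"{gid}  {row.temporal_class:>8}   "
          f"{results.i_table.loc[gid, 0]:7.3f}/{row['I_0']:<7.3f}  "
          f"{est.half_life_min:8.2f}/{row['thalf_0']:<8.2f}   "
          f"{est.termination_fraction:10.3f}/{row['f_0']:<10.3f}")

i_err = float(np.max(np.abs(results.i_table[0] -
                            truth.loc[results.i_table.index, "I_0"])
                     / truth.loc[results.i_table.index, "I_0"]))
ok = table0[table0.status == "ok"]
hl_err = float(np.max(np.abs(ok.half_life_min - truth.loc[ok.index, "thalf_0"])
                      / truth.loc[ok.index, "thalf_0"]))
print(f"\nmax relative error, productive initiation I: {i_err:.2e}")
print(f"max relative error, Pol II half-life t1/2:   {hl_err:.2e}")
print("\nWith noise-free unit-calibrated signals the estimators invert the")
print("forward model exactly: errors at machine precision mean every step")
print("(normalization, pause calling, windowing, fitting) is self-consistent.")
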