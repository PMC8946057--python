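"""Median-stratified survival analysis on a synthetic cohort.

Samples above their cohort's median NCS carry a doubled hazard by
construction; the analysis splits each cohort at the median, runs the
log-rank test and a univariate Cox model, and reads five-year survival off
the Kaplan-Meier curves.
"""

import numpy as np

from cinscore import GeneratorConfig, simulate_cohort, survival_by_cohort
from cinscore.survival import response_test

ds = simulate_cohort(GeneratorConfig(seed=5, n_cohorts=6,
                                     samples_per_cohort=80))

res = survival_by_cohort(ds.scores, ds.annotations, score="ncs", endpoint="os")
print("per-cohort overall survival, high vs low NCS (median split):")
for _, r in res.iterrows():
    print(f"  {r['cohort']}: HR={r['hazard_ratio']:.2f} "
          f"({r['hr_ci_low']:.2f}-{r['hr_ci_high']:.2f}), "
          f"log-rank p={r['logrank_p']:.3g}, "
          f"5-y survival high/low = "
          f"{r['five_year_high']:.2f}/{r['five_year_low']:.2f}")

sig = (res["logrank_p"] < 0.05).sum()
print(f"\n{sig} of {len(res)} cohorts significant at p<0.05 "
      f"(planted hazard ratio 2; median HR {np.median(res['hazard_ratio']):.2f})")

scores = ds.scores.set_index("sample_id")
stat, p, med_r, med_n = response_test(
    scores["ncs"], ds.annotations["response"].reindex(scores.index)
)
print(f"\ntherapy response (Wilcoxon rank-sum on NCS): p = {p:.2e}; "
      f"median NCS responders {med_r:.0f} vs non-responders {med_n:.0f}")
print("Responders were generated with lower NCS, mirroring a higher "
      "response rate\nin numerically stable tumours.")
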