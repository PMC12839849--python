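"""Build and validate the prognostic risk model on the signature.

Univariate Cox screen -> multivariate Cox -> linear risk score -> Youden
cutoff on the 5-year IPCW ROC -> KM / log-rank / HR / C-index / AUCs.
"""

import warnings

warnings.filterwarnings("ignore")

from cmsig import run_discovery

run = run_discovery(seed=7)
m = run.metrics
rep = run.report

print(f"screen retained {m['n_screen_retained']}/{m['signature_size']} signature genes")
print(f"risk cutoff (max Youden, 5-year horizon): {m['cutoff']:+.3f}")
n_high = int((run.assignment.group == "high").sum())
print(f"risk groups: {n_high} high / {len(run.assignment.sample_ids) - n_high} low")
print(f"log-rank p = {rep.logrank_p:.2e}")
hr = rep.hazard_ratio
print(f"high-vs-low HR = {hr['hr']:.2f} [{hr['ci_low']:.2f}-{hr['ci_high']:.2f}]")
print(f"C-index = {rep.c_index:.3f}")
print("AUC at 2/3/5 years:",
      " / ".join(f"{rep.auc[h]:.3f}" for h in (24.0, 36.0, 60.0)))
km_high, km_low = rep.km["high"], rep.km["low"]
print(f"5-year survival: high {km_high.survival[km_high.times <= 60][-1]:.2f}, "
      f"low {km_low.survival[km_low.times <= 60][-1]:.2f}")
# An HR well above 2 with a tiny log-rank p reproduces, on synthetic data,
# the qualitative separation the risk score is designed to deliver.
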