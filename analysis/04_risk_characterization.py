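"""Risk characterization: TEQ, EDI, MOE and critical intakes per commodity.

Runs the TEF-weighted exposure chain on the survey means for both indices
(BaP alone and the PAH4 set) and both intake scenarios (mean and 95th
percentile), classifies each margin against the 10⁴ threshold, and reports
the consumption at which the margin would fall to that threshold.
"""

import pandas as pd

from pahrisk import io
from pahrisk.config import default_config
from pahrisk.pipeline import risk_stage

cfg = default_config(seed=20260927, outdir="results")
table4 = pd.read_csv("results/summary_table4.csv")
risk = risk_stage(table4, cfg)
io.write_table(risk, "results/risk_table6.csv")

show = risk[
    ["commodity", "teq_bap_ug_kg", "teq_sum4_ug_kg", "moe_bap_mean", "moe_bap_p95",
     "critical_intake_bap_g_day"]
].copy()
for col in ("moe_bap_mean", "moe_bap_p95"):
    show[col] = show[col].map(lambda v: f"{float(v):.2e}" if v != ">1e12" else v)
print(show.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

elevated = [
    c for c in risk.columns if c.startswith("concern_") for v in [risk[c]] if (v == "elevated").any()
]
print(f"cells of elevated concern (MOE < {cfg.risk.moe_threshold:.0e}): "
      f"{'none' if not elevated else elevated}")
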