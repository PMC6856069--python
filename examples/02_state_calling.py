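"""Beta/M conversion and hyper/hypo state calling on a toy matrix.

M = log2(beta / (1 - beta)); the +/-2 M cutoffs are the same thresholds as
beta 0.8 / 0.2.  A probe is hyper- (hypo-) methylated in a group when the
group's mean M is at or above +2 (at or below -2).
"""

import pandas as pd

import methtopo as mt
from methtopo.core import MethylationMatrix, SampleSheet

for beta in (0.2, 0.5, 0.8):
    print(f"beta {beta:.1f} -> M {mt.beta_to_m(beta):+.2f}")

beta = MethylationMatrix(
    pd.DataFrame(
        {"s1": [0.92, 0.50, 0.10], "s2": [0.88, 0.55, 0.12]},
        index=["cg_body", "cg_mid", "cg_prom"],
    ),
    scale="beta",
)
sheet = SampleSheet(
    pd.DataFrame({"group": ["tumor", "tumor"], "platform": ["A450K", "A450K"]},
                 index=pd.Index(["s1", "s2"], name="sample_id"))
)
means = mt.group_mean_m(mt.matrix_to_m(beta), sheet, "tumor")
calls = mt.call_states(means, group="tumor")
for probe in beta.probe_ids:
    print(f"{probe}: mean M {means[probe]:+.2f} -> {calls.states[probe]}")

# cg_body sits near beta 0.9 (M ~ +3.2) and is called hyper; cg_prom near
# beta 0.1 (M ~ -3.1) is hypo; the intermediate probe is neither.
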