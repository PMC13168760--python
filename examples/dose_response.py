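"""Drug-response screening: simulated dose ladders -> trend and effect sizes.

Generates cohorts under an atrophy-inducing glucocorticoid scenario
(force decreases with dose) and an anabolic androgen scenario (force
increases), extracts twitch forces, and summarizes per-dose means, ratios
to vehicle, the monotonic-trend flag, and Cohen's d / eta-squared.
"""

import pandas as pd

from pillarforce.contractility import contraction_metrics, dose_response_summary, effect_sizes
from pillarforce.synthetic import DEX_SCENARIO, TES_SCENARIO, generate_cohort

for name, scenario in (("dexamethasone", DEX_SCENARIO), ("testosterone", TES_SCENARIO)):
    bundle = generate_cohort(scenario, n_per_group=5, seed=0)
    manifest, protocol = bundle["manifest"], bundle["protocol"]
    rows = []
    for _, r in manifest.iterrows():
        m = contraction_metrics(bundle["traces"][r["tissue_id"]], protocol)
        rows.append({"dose": "vehicle" if r["dose"] == 0 else r["dose"],
                     "force_un": m.twitch_amplitude_un,
                     "condition": r["condition"]})
    df = pd.DataFrame(rows)
    table, trend = dose_response_summary(df)
    print(f"\n{name}: twitch-force trend = {trend}")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    vehicle = df.loc[df["dose"] == "vehicle", "force_un"]
    top = df.loc[df["dose"] == 1.0, "force_un"]
    d, eta2 = effect_sizes(top, vehicle)
    print(f"top dose vs vehicle: Cohen's d = {d:.2f}, eta^2 = {eta2:.2f}")
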