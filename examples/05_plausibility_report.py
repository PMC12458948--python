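"""Rule-based plausibility and cross-session consistency reporting.

Takes an inferred cell-type distribution resembling a human cortical
cohort (pyramidal-dominant, sizable Unknown mass, small interneuron
fractions), checks it against the shipped reference range for cortical SST
interneurons (4-9%), and measures label agreement between two sessions.
"""

import numpy as np

import spikesight as ss

rng = np.random.default_rng(0)
labels = rng.choice(
    ["Pyramidal", "Unknown", "SST", "GABA_nonSST"], size=4000, p=[0.512, 0.35, 0.075, 0.063]
)
proportions = ss.compute_type_proportions(labels)
report = ss.check_plausibility(proportions, region="cortex")
print("observed cell-type proportions (%):")
for t, pct in proportions.items():
    if pct > 0:
        verdict = report.verdicts.get(t, "unknown-mass")
        print(f"  {t:12s} {pct:5.2f}  -> {verdict}")
print(f"overall flag raised: {report.overall_flag}")

session_a = {f"u{i}": l for i, l in enumerate(labels[:200])}
session_b = dict(session_a)
for uid in list(session_b)[:8]:
    session_b[uid] = "Unknown"  # 4% of units change label across days
agreement = ss.cross_session_agreement(session_a, session_b, session_a.keys())
print(f"cross-session agreement: {100 * agreement.overall_agreement:.1f}% "
      f"over {agreement.n_matched_units} matched units")
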