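"""Anchor the fitted timeline, stage an unseen cohort, and predict time to
clinical onset against the CAG/age survival benchmark.

Staging places an individual on the anchored timeline (t = 0 is the
manifest-group abnormality threshold) from their adjusted volumes alone; the
predicted time to onset is minus the stage. The survival benchmark predicts
onset from age and CAG repeat count only. In this generator CAG carries no
timing information, so staging should win decisively.
"""

import numpy as np
import pandas as pd

import hdprogression as h

# train
cfg = h.GeneratorConfig(n_per_group={"HC": 100, "PreHD": 95, "HD": 55}, seed=42)
cohort, truths = h.generate_cohort(cfg)
adjustment = h.fit_adjustment(cohort)
directions = {r.name: r.direction for r in cfg.regions}
adjusted = h.apply_adjustment(cohort, adjustment, directions)
gene = adjusted.subset([t.subject_id for t in truths if t.group != "HC"])
model = h.fit(gene, h.ModelConfig(seed=1))
anchored = h.anchor_timeline(model, h.hd_baseline_means(gene))

# unseen premanifest cohort, adjusted with the TRAINING adjustment model
tcfg = h.GeneratorConfig(n_per_group={"HC": 40, "PreHD": 120, "HD": 0}, seed=99)
tcohort, ttruths = h.generate_cohort(tcfg)
tadj = h.apply_adjustment(tcohort, adjustment, directions)
tgene = tadj.subset([t.subject_id for t in ttruths if t.group != "HC"])
stages = h.stage_cohort(anchored, tgene)
print(f"staged {len(stages)} unseen premanifest subjects; "
      f"mean stage = {stages['stage'].mean():+.2f} years (negative = pre-onset)")

grid, dens = h.group_density(stages["stage"].to_list())
print(f"stage density peaks at {grid[np.argmax(dens)]:+.2f} years")

# converters: conversion is detected only at annual visits (interval censoring)
pairs = []
for t in ttruths:
    if t.group == "PreHD":
        actual = h.censored_time_to_onset(t, visit_interval=1.0, horizon=15.0)
        if actual is not None and actual > 0:
            pairs.append((t.subject_id, actual))
stage_by_id = stages.set_index("subject_id")["stage"]
preds = [h.predict_onset(stage_by_id[s]) for s, _ in pairs]
acts = [a for _, a in pairs]
gppm_eval = h.evaluate_onset(preds, acts, [s for s, _ in pairs], label="GPPM")

truth_by_id = {t.subject_id: t for t in ttruths}
sm_in = pd.DataFrame({
    "subject_id": [s for s, _ in pairs],
    "current_age": [truth_by_id[s].baseline_age for s, _ in pairs],
    "cag": [truth_by_id[s].cag for s, _ in pairs],
})
sm_pred = h.predict_onset_sm(sm_in, n_samples=10_000, seed=5)
sm_eval = h.evaluate_onset(sm_pred["predicted"].to_numpy(), acts,
                           [s for s, _ in pairs], label="SM")

print(f"\n{len(pairs)} converters (onset observed at annual visits):")
print(h.compare_models(gppm_eval, sm_eval).round(2))
print("\nResidual = predicted - actual years to onset. The staging model's")
print("mean residual is positive: conversion is recorded late (interval")
print("censoring) relative to the volumetric abnormality threshold. The")
print("survival benchmark trails because CAG is uninformative here.")
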