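"""Generate a synthetic HD cohort, fit the progression model, and print the
recovered disease timeline.

The cohort mimics a large observational imaging study: ~100 controls and 150
gene carriers (premanifest + manifest), three annual visits, ten regional
brain volumes with covariate effects, a shared anatomical intercept and
measurement noise. Because the generator's latent state is known, the script
prints recovered-vs-true time-shifts and change-point times.
"""

import numpy as np

import hdprogression as h

cfg = h.GeneratorConfig(n_per_group={"HC": 100, "PreHD": 95, "HD": 55}, seed=42)
cohort, truths = h.generate_cohort(cfg)
print(f"cohort: {len(cohort)} rows ({cohort['subject_id'].nunique()} subjects x 3 visits)")

# covariate-adjust against the control group and direction-normalize
adjustment = h.fit_adjustment(cohort)
directions = {r.name: r.direction for r in cfg.regions}
adjusted = h.apply_adjustment(cohort, adjustment, directions)
gene = adjusted.subset([t.subject_id for t in truths if t.group != "HC"])

model = h.fit(gene, h.ModelConfig(seed=1))

true_shift = np.array([t.time_shift for t in truths if t.group != "HC"])
r = np.corrcoef(true_shift, model.shifts)[0, 1]
err = model.shifts - (true_shift - true_shift.mean())
print(f"time-shift recovery: Pearson r = {r:.3f}, "
      f"median |error| = {np.median(np.abs(err)):.2f} years")
print("  (each gene carrier's position on the common disease timeline,")
print("   estimated from three annual visits, versus the simulated truth)")

# order regions by the time their trajectory changes fastest
samples = h.sample_all_regions(model, model.support_grid(0.05), 1000, seed=7)
control_stats = {reg: (adjustment.hc_raw_mean[reg], adjustment.hc_resid_sd[reg])
                 for reg in model.regions}
cp = h.change_points(samples, control_stats=control_stats)
mbar = true_shift.mean()
print("\nregional cascade (change point = time of maximal gradient,")
print("years on the generator's onset-anchored scale; magnitude = % of control mean):")
truth_ct = {reg.name: reg.change_time for reg in cfg.regions}
for _, row in cp.table.sort_values("mean_time").iterrows():
    name = row["region"]
    print(f"  {name:20s} recovered {row['mean_time'] + mbar:+6.2f} y "
          f"(true {truth_ct[name]:+5.1f})   magnitude {row['mean_magnitude']:5.1f} %")
print("\nThe striatum (caudate, putamen, pallidum) leads the cascade, the")
print("cortical regions follow, and the lateral ventricles enlarge late --")
print("the qualitative ordering the generator encodes.")
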