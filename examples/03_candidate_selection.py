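"""Stage 2: candidate space, volume filter, post-double-selection LASSO.

Enumerates >500 candidate terms (mains + all pairwise and base-characteristic
interactions), drops terms without 50 carriers per treatment arm, then runs
rigorous LASSO on the treatment and outcome models and keeps the union.
"""

import hetiv

cfg = hetiv.SimulationConfig(n_patients=24_312, seed=1)
cohort, _ = hetiv.generate_cohort(cfg)

survey = hetiv.simulate_survey(list(cfg.comorbidity_prevalences), seed=2)
priorities = hetiv.aggregate_ratings(survey)
cands = hetiv.enumerate_candidates(priorities)
kept, report = hetiv.apply_volume_threshold(cohort, cands, min_per_arm=50)
selection = hetiv.pds_select(cohort, kept, priorities)

print(f"candidate terms: {len(cands)} (interactions: {len(cands.group_d)})")
print(f"past the 50-per-arm volume filter: {len(kept)}")
print(f"selected in the treatment model: {len(selection.x_selected_d)}")
print(f"selected in the outcome model:   {len(selection.x_selected_y)}")
print(f"treatment-interaction terms kept: {len(selection.selected_interactions)}")
print(f"final modifier set (union with forced): {len(selection.x_selected)}")
print("dropped example:",
      report.table.loc[~report.table["passed"], "term"].head(3).tolist())
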