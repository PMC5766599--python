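"""Paired discovery DE, unpaired confirmation DE, and the confirmation chain.

Simulates a 3-pair matched discovery cohort plus a larger unpaired
confirmation cohort, runs the negative-binomial likelihood-ratio test on
both, and intersects the results at the pipeline's standard thresholds
(discovery FDR < 0.2, confirmation FDR < 0.05, concordant direction).
"""

from lnckit import (
    SimulationConfig,
    annotate_novelty,
    confirm,
    lrt_group_test,
    lrt_paired_test,
    partition_by_direction,
    simulate_confirmation_cohort,
    simulate_discovery_cohort,
)

cfg = SimulationConfig(
    n_features=800, n_true_de=60, planted_set_size=12,
    n_tumor_confirm=150, n_normal_confirm=30, seed=7,
)
counts_d, sheet_d, annotation, truth = simulate_discovery_cohort(cfg)
counts_c, sheet_c = simulate_confirmation_cohort(cfg, truth)

disc = lrt_paired_test(counts_d, sheet_d)
conf = lrt_group_test(counts_c, sheet_c)
hits = confirm(disc, conf, fdr_disc=0.2, fdr_conf=0.05, annotation=annotation)
hits = annotate_novelty(hits, known_ids=set())
up, down = partition_by_direction(hits)

n_true = int(truth["is_de"].sum())
recovered = len(set(hits["feature_id"]) & set(truth.loc[truth["is_de"], "feature_id"]))
print(f"discovery cohort: {int(disc['tested'].sum())} features tested on 3 pairs")
print(f"confirmed hits:   {len(hits)} ({len(up)} up, {len(down)} down)")
print(f"truth:            {recovered}/{n_true} planted DE features recovered, "
      f"{len(hits) - recovered} false confirmations")
print("Confirmed = significant in BOTH cohorts with the same direction; the")
print("lenient discovery threshold is rescued by the stricter confirmation one.")
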