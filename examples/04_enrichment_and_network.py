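"""Correlation-rank enrichment and the lncRNA-mRNA co-expression network.

Simulates a confirmation cohort with a latent factor co-expressing one
target lncRNA with a planted protein-coding gene set, ranks all genes by
Pearson correlation with the target across tumor samples, tests the set
for a rank shift, and builds the percentile-thresholded bipartite network.
"""

from lnckit import (
    SimulationConfig,
    build_network,
    correlate_target_vs_all,
    hub_report,
    lrt_group_test,
    lrt_paired_test,
    planted_gene_set,
    rank_set_enrichment,
    select_vertices,
    simulate_confirmation_cohort,
    simulate_discovery_cohort,
    target_lncrna,
)

cfg = SimulationConfig(
    n_features=1000, n_true_de=80, planted_set_size=15,
    n_tumor_confirm=200, n_normal_confirm=40, seed=11,
)
counts_d, sheet_d, annotation, truth = simulate_discovery_cohort(cfg)
counts_c, sheet_c = simulate_confirmation_cohort(cfg, truth)
target = target_lncrna(truth)
members = planted_gene_set(truth).members("SET:PLANTED")

ranking = correlate_target_vs_all(counts_c, target, sheet=sheet_c, sample_subset="tumor")
enr = rank_set_enrichment(ranking, members, set_id="SET:PLANTED")
print(f"target lncRNA {target}: ranked {len(ranking.table)} genes over "
      f"{ranking.n_samples} tumor samples")
print(f"planted set ({enr.set_size} genes): mean rank {enr.mean_rank_set:.0f} vs "
      f"background {enr.mean_rank_background:.0f}, one-sided p={enr.p_one_sided:.3g}")

disc = lrt_paired_test(counts_d, sheet_d)
conf = lrt_group_test(counts_c, sheet_c)
vertices = select_vertices(disc, conf, annotation)
net = build_network(counts_c, sheet_c, vertices, edge_fraction=0.005)
hubs = hub_report(net, top_k=3)
print(f"network: {net.graph.number_of_nodes()} vertices, "
      f"{net.graph.number_of_edges()} edges (top 0.5% per correlation sign)")
for row in hubs.itertuples(index=False):
    tag = " <- target" if row.feature_id == target else ""
    print(f"  hub {row.feature_id}: degree {row.degree} "
          f"({row.n_positive}+/{row.n_negative}-){tag}")
print("A tiny enrichment p and the target emerging as top hub show the")
print("latent co-expression structure is recovered from counts alone.")
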