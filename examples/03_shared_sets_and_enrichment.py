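"""Find gene sets dysregulated in more than one disorder, tally the Venn
regions, and test candidate-gene enrichment.

A shared set is planted: the same genes are variance-inflated in both AUT
and SCZ cases.  After screening each disorder separately, the set is
significant in both, so Jaccard clustering (cut 0.3) groups its two
occurrences into one AUT+SCZ cluster.
"""

from aberex import (
    CohortBundle, CohortConfig, cluster_shared_sets, generate_candidate_lists,
    generate_cohort, generate_gene_sets, hypergeom_enrichment,
    restrict_to_background, run_screen, split_by_disorder, venn_counts,
)

cfg = CohortConfig(n_genes=600, n_aut=30, n_scz=25, n_bpd=8,
                   n_controls_batch1=40, n_controls_batch2=30,
                   n_modules=0, sets_per_disorder=1, set_size=10,
                   tau=3.0, shared_set_combos=(("AUT", "SCZ"),),
                   n_hidden=0, batch_sd=0.0)
expr, samples, truth = generate_cohort(cfg, seed=2)
coll = restrict_to_background(
    generate_gene_sets(truth, expr.index, n_decoys=30, size_range=(8, 14),
                       seed=2),
    expr.index)
bundles = split_by_disorder(CohortBundle(expr, samples))

significant = {}
for i, d in enumerate(("AUT", "SCZ")):
    res = run_screen(bundles[d], coll, n_perm=200, seed=10 + i,
                     p_cutoff=0.01, compute_delta="none")
    significant[d] = [(n, coll[n].members) for n in res.significant]
    print(f"{d}: {len(res.significant)} significant set(s): "
          f"{sorted(res.significant)}")

clusters, _ = cluster_shared_sets(significant, cut=0.3)
for combo, n in sorted(venn_counts(clusters).items()):
    print(f"  clusters significant in {'+'.join(combo)}: {n}")

# candidate-gene enrichment of the shared set against the analyzed universe
candidates = generate_candidate_lists(truth, expr.index,
                                      enrichment_factor=10.0, seed=2)
shared = truth.planted_aberrant_sets[-1]
enr = hypergeom_enrichment(shared.genes, candidates["AUT"], expr.index,
                           set_name=shared.name)
print(f"\n{enr.set_name}: {enr.overlap}/{enr.set_size} genes on the AUT "
      f"candidate list (hypergeometric P = {enr.p_hyper:.2e})")
# The P-value is the upper tail P(X >= k) of drawing the observed overlap
# given the candidate-list size and the analyzed-gene background.
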