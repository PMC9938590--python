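"""Peak-set co-localization by length-preserving permutation testing.

Compares a query peak set against a planted-coincident target and an
independent target; prints observed/expected overlaps, fold enrichment
and the add-one empirical p (minimum 1/101 at 100 permutations).
"""

import proxitome as px

sizes = px.ChromSizes({f"chr{i + 1}": 400_000 for i in range(4)})

query, coincident = px.generate_peak_sets(sizes, 50, 50, "coincident",
                                          offset_sd=0.0, seed=3)
coincident.label = "planted_coincident"
_, independent = px.generate_peak_sets(sizes, 50, 50, "independent", seed=4)
independent.label = "independent"

table, summary = px.batch_overlap(query, [coincident, independent], sizes,
                                  n_permutations=100, seed=5)
print(table[["observed", "expected", "fold_enrichment", "p_empirical",
             "significant"]].round(3).to_string())
print(f"targets significant: {summary['targets_significant']} of "
      f"{summary['targets_tested']}")
# The planted target reaches the minimum empirical p (1/101 ~ 0.0099) with
# a large fold enrichment; the independent target hovers near fold 1.
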