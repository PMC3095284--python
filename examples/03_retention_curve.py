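"""Choose a core size from an allele-retention curve.

Sweeps nominal core sizes, records how many of the collection's alleles
each size's stable set retains, and picks the smallest size clearing the
80% threshold -- the standard minimum requirement for a core collection.
"""

import corekit as ck

G, _ = ck.simulate_structured_population(ck.SimulationConfig(seed=1))
D = ck.distance_matrix(G)

curve = ck.retention_curve(G, D, sizes=range(25, 301, 25), reps=100, seed=101)
print(curve.to_frame().to_string(index=False,
                                 formatters={"retention_pct": "{:.1f}".format,
                                             "mean_GD": "{:.3f}".format}))

k = ck.choose_core_size(curve, threshold=80.0)
i = curve.sizes.index(k)
print(f"\nsmallest size retaining >= 80%: k = {k} "
      f"(stable set {curve.stable_sizes[i]} accessions, "
      f"{curve.retention_pct[i]:.1f}% of alleles) "
      f"= {100 * curve.stable_sizes[i] / G.n_accessions:.1f}% of the collection")
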