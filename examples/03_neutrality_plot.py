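"""Neutrality plot: partitioning codon-usage bias into mutation vs selection.

Generates genomes with a spread of base compositions, regresses GC12 on GC3
across them, and reads the slope as the percentage contribution of mutation
pressure (slope x 100) versus selection.
"""

from mitocomp.neutrality import neutrality_partition, neutrality_points, ols_fit
from mitocomp.synthetic_data import SyntheticSpec, make_mitogenome

records = []
for i, at in enumerate((0.66, 0.70, 0.74, 0.78, 0.82, 0.86, 0.90)):
    records.append(
        make_mitogenome(SyntheticSpec(seed=31, at_target=at,
                                      codon_dirichlet_alpha=5.0), i)
    )

points = neutrality_points(records)
for rec, (gc3, gc12) in zip(records, points):
    print(f"{rec.id}:  GC3 {100 * gc3:5.1f}%   GC12 {100 * gc12:5.1f}%")

fit = ols_fit(points)
part = neutrality_partition(fit)
print(f"\nOLS: slope {fit.slope:.4f}, r {fit.r:.3f}, "
      f"F {fit.F_stat:.2f}, p {fit.p_value:.2g}")
print(f"mutation pressure {part.mutation_pct:.2f}%  |  "
      f"natural selection {part.selection_pct:.2f}%")
print("\nA slope near 1 means mutation moves all codon positions together;"
      "\nnear 0, selection pins the first two positions while GC3 drifts."
      "\nThese genomes mutate without protein-level constraint, so the slope"
      "\nsits near (or, with noise, beyond) 1; out-of-range slopes are"
      "\nreported as-is with a warning.")
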