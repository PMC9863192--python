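"""RSCU and the effective number of codons for a biased genome.

Pools the 13 protein-coding genes of a synthetic genome, computes relative
synonymous codon usage under the invertebrate mitochondrial code, counts
over-/under-represented codons (RSCU > 1.6 / < 0.6), and compares Wright's
ENC with its expected value under pure mutation pressure at the observed
GC3.
"""

from mitocomp.codon_usage import (
    count_codons, enc, enc_expected, gc_positions, rscu, rscu_class_report,
)
from mitocomp.mito_io import extract_partition
from mitocomp.synthetic_data import SyntheticSpec, make_mitogenome

record = make_mitogenome(SyntheticSpec(seed=7, codon_dirichlet_alpha=0.15), 0)
cds = [seq for _, seq in extract_partition(record, "PCG")]
summary = count_codons(cds)
values = rscu(summary)
report = rscu_class_report(summary)
gc1, gc2, gc3, gc12 = gc_positions(summary)
enc_obs = enc(summary)

print(f"{record.id}: {summary.n_codons} sense codons in 13 PCGs")
for cls in ("overrepresented", "underrepresented", "unused"):
    print(f"  {cls:<17} {report[cls]['count']:>3} codons"
          + (f"  (mean RSCU {report[cls]['mean_rscu']:.2f})"
             if report[cls]["count"] else ""))
top = sorted(values.items(), key=lambda kv: -kv[1])[:5]
print("  most preferred codons:",
      ", ".join(f"{c} ({v:.2f})" for c, v in top))
print(f"\nGC3 {100 * gc3:.1f}%  GC12 {100 * gc12:.1f}%")
print(f"ENC observed {enc_obs:.2f} vs {enc_expected(gc3):.2f} expected under "
      "mutation alone")
print("\nENC = 20 means one codon per amino acid (extreme bias); 62 means all"
      "\nsense codons equally used. Observed << expected marks strong bias"
      "\nbeyond what AT-rich mutation pressure alone would produce.")
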