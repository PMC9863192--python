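"""Base composition and strand skews of a synthetic AT-rich mitogenome.

Builds one annotated genome emulating a soft-scale insect mitogenome
(~86% A+T) and prints per-partition composition: the A+T content is the
headline statistic of these genomes, and the AT/GC skews measure which
strand accumulates which bases.
"""

from mitocomp.composition import composition_summary
from mitocomp.mito_io import PARTITIONS
from mitocomp.synthetic_data import SyntheticSpec, make_mitogenome

record = make_mitogenome(SyntheticSpec(seed=7, at_target=0.86), 0)
print(f"{record.id}: {record.length} bp, {len(record.features)} features\n")
print(f"{'partition':<10}{'bp':>7}{'A+T %':>8}{'AT skew':>9}{'GC skew':>9}")
for part in PARTITIONS:
    s = composition_summary(record, part)
    print(f"{part:<10}{s.length_bp:>7}{100 * s.at_content:>8.1f}"
          f"{s.at_skew:>9.3f}{s.gc_skew:>9.3f}")

print(
    "\nA+T near 86% reproduces the extreme AT richness of scale-insect"
    "\nmitogenomes; skews are (A-T)/(A+T) and (G-C)/(G+C) on the majority strand."
)
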