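"""Gene-order comparison: shared adjacencies and breakpoint distances.

Generates genomes with increasing numbers of tRNA-block rearrangements away
from the ancestral insect gene order and measures how many gene junctions
survive.
"""

from mitocomp.gene_order import (
    breakpoint_distance, extract_order, order_matrix, order_to_string,
    shared_adjacencies,
)
from mitocomp.synthetic_data import SyntheticSpec, make_mitogenome

ancestral = make_mitogenome(SyntheticSpec(seed=61, n_rearrangements=0), 0)
orders = [extract_order(ancestral)]
for k in (1, 3, 6):
    rec = make_mitogenome(SyntheticSpec(seed=61, n_rearrangements=k), k)
    orders.append(extract_order(rec))

ref = orders[0]
print("ancestral order:", order_to_string(ref)[:72], "...")
print("\nrearrangements  breakpoint distance  shared adjacencies (of 37)")
for k, o in zip((0, 1, 3, 6), orders):
    d = breakpoint_distance(ref, o)
    s = len(shared_adjacencies(ref, o))
    print(f"{k:>14}  {d:>19}  {s:>18}")

dist, freq = order_matrix(orders)
universal = freq[freq.frequency == 1.0]
print(f"\n{len(universal)} adjacencies conserved across all 4 genomes, e.g.:")
print("  " + ", ".join(universal.adjacency.head(6)))
print("\nRearrangement confined to tRNA blocks leaves the protein-coding and"
      "\nrRNA backbone junctions (e.g. atp8|atp6) intact, as in real insects.")
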