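# Methods

This note records the models and statistics mitocomp implements, the
conventions it fixes where the literature leaves room, and what the
synthetic-data generator does and does not emulate.

## Genome model and I/O

A mitogenome is held as the majority (J) strand sequence of the circular
molecule plus a coordinate-sorted list of typed, stranded features.
Coordinates are 1-based inclusive (GenBank convention). A feature crossing
the replication origin is stored with a `wraps_origin` flag rather than as
a split location; its sequence is the tail..head concatenation, reverse
complemented when the feature lies on the minority (N) strand.

Conventions fixed here:

* **Gene names** are normalised to 37 canonical tokens. The leucine and
  serine tRNA pairs are resolved by an explicit codon-family tag in the
  label (e.g. `tRNA-Leu(UUR)` → `trnL2`), failing that by the anticodon
  qualifier (UAA→L2, UAG→L1, UCU/GCU→S1, UGA→S2), failing that the
  feature is kept with name `?` — records in public archives genuinely
  vary, and guessing would silently corrupt gene-order comparisons.
* **Control region**: an annotated D-loop when present; otherwise the
  longest unannotated circular span of at least 200 bp. The threshold
  separates the control region from ordinary intergenic spacers, which in
  these genomes run up to a few tens of bp.
* **Alphabet**: A/C/G/T/N only. N is tolerated and excluded from every
  composition denominator and from codon statistics; other IUPAC
  ambiguity codes are rejected at parse time rather than silently
  miscounted.

## Composition and skews

Base fractions, A+T content, and the Perna–Kocher strand skews
AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C) are computed on the majority
strand — for partitions, on the concatenation of the features as they lie
on that strand, *without* reverse-complementing minus-strand genes, since
strand asymmetry is exactly what the skews measure. Zero denominators are
flagged (NaN), never coerced to 0.

Group differences use a two-sided Mann–Whitney U test by default; a rank
test stays meaningful at the group sizes these studies actually have
(n = 5 against a few hundred). Welch's t-test is available behind a flag.
Significance tiers follow the field's convention: `***` p < 0.01,
`**` p < 0.05, `ns` otherwise. When every observation is identical the
test degenerates and p = 1 is reported directly. Singleton groups are
flagged unreliable.

## Codon usage

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial): stops TAA/TAG only, TGA=Trp, AGA/AGG=Ser, ATA=Met, hence
62 sense codons whose synonymous families partition into twelve 2-fold
and six 4-fold families plus 6-fold Leu and 8-fold Ser. The code is a
parameter, so the standard code remains usable.

* **Counting** reads each CDS in frame from position 1, drops a trailing
  incomplete codon (mitochondrial genes commonly end in a truncated
  T/TA stop completed by polyadenylation), tallies stop codons separately
  (excluded from all statistics), skips codons containing N, and warns on
  internal stops.
* **RSCU** is observed count over the family-uniform expectation; family
  sums equal the family size exactly whenever the family is used.
  Classification uses strict inequalities at 1.6 (overrepresented) and
  0.6 (underrepresented); a count of 0 in a used family is "unused", an
  entirely absent family is flagged rather than scored.
* **GC1/GC2/GC3** include all sense codons (Met and Trp included);
  GC12 is the exact mean of GC1 and GC2. A synonymous-only GC3 variant is
  deliberately not the default: tool conventions differ, and the simple
  all-codon convention is stated rather than guessed.
* **ENC** follows Wright's estimator with degeneracy classes derived from
  the active code's true family sizes — under table 5 these are
  {2-fold × 12, 4-fold × 6, 6-fold Leu, 8-fold Ser}, so the analytic
  floor is 12 + 6 + 1 + 1 = 20 and the no-bias ceiling is the 62 sense
  codons (not the standard code's 61). Per family with total count ≥ 2,
  F̂ = (nΣp² − 1)/(n − 1); non-positive F̂ are excluded; an empty 6- or
  8-fold class borrows the 4-fold mean (logged); results are clipped to
  [20, 62]. Because F̂ grows with n toward Σp², ENC decreases
  monotonically as a fixed usage pattern is scaled up, converging to the
  infinite-sample value — the finite-sample correction only ever inflates
  ENC.
* **Expected ENC under pure mutation** uses Wright's published curve
  ENC*(s) = 2 + s + 29/(s² + (1−s)²) with s = GC3, extended by continuity
  at s ∈ {0, 1}. Note two fine points: the curve's maximum sits at
  s ≈ 0.502, not exactly 0.5, because of the linear term; and the curve
  encodes the *standard* code's class structure. The table-5 analogue of
  the no-bias expectation is 31/(s² + (1−s)²), up to ~1.5 ENC units
  higher near s = 0.5; unbiased table-5 usage therefore sits slightly
  *above* the standard curve, and only points clearly below it should be
  read as a selection signal.

## Neutrality plot

Each species contributes one (GC3, GC12) point, pooled over its 13
concatenated protein-coding genes on their coding strands — species-level
pooling matches how these plots are drawn, and concatenation weights genes
by length rather than equally. Simple OLS is computed in closed form; the
slope's significance is reported as F = r²(n−2)/(1−r²) on (1, n−2) df, the
reporting style usual for these plots. The mutation/selection partition is
mutation % = 100 × slope, selection % = 100 − mutation %, an exact
complement. Slopes outside [0, 1] are reported as-is with a warning: the
percentage reading breaks down there, and small samples or generators
whose GC12 responds more than GC3 produce such slopes legitimately.

## Ka/Ks (Nei–Gojobori)

Homologous genes are aligned at the protein level (global
Needleman–Wunsch, BLOSUM62, gap open −10 / extend −1, via Biopython's
pairwise aligner; the first optimal alignment of the deterministic DP is
used) and back-translated, so gaps always occupy whole codons. Counting
follows Nei & Gojobori (1986) with equal pathway weighting:

* potential synonymous sites per codon = 3 × (synonymous one-step changes
  / one-step changes that do not create a stop), averaged over the two
  aligned codons, so N + S = 3 × (aligned codon pairs) exactly;
* codon pairs differing at k positions average their synonymous /
  nonsynonymous step counts over all k! orderings that avoid stop-codon
  intermediates; if every complete pathway is blocked, the pair falls
  back to its valid direct single-position changes (logged — essentially
  unreachable under real codes);
* pN = Nd/N and pS = Sd/S are Jukes–Cantor corrected,
  d = −(3/4)ln(1 − 4p/3), undefined at p ≥ 3/4 (saturation).

Gap codons, codons containing N, and stop codons are excluded pairwise.
The ratio is undefined on identical sequences (0/0), infinite (flagged,
regime "positive") when Ks = 0 < Ka; regime calls compare the ratio to 1
with tolerance 1e−9. Per-gene group summaries average the defined finite
pairwise ratios by default ("mean of ratios"); the "ratio of means"
(mean Ka / mean Ks) alternative is exposed because published "average
Ka/Ks" values are ambiguous between the two. This is count-based
Nei–Gojobori, not a maximum-likelihood codon model: exact numerical
agreement with other packages' defaults is not guaranteed, though regime
calls are robust.

## Gene order

Orders are signed circular permutations over the canonical genes (control
region excluded by default — it is length-variable and often
unannotated). Orders are rotation-normalised to start at cox1 when
present. An adjacency is the ordered signed pair of neighbours; since
circular DNA has no intrinsic reading direction, (+x, +y) and (−y, −x)
encode the same junction and are canonicalised together (preferring the
reading whose first gene is on the majority strand). The breakpoint
distance on a common gene set is the count of adjacencies of one order
absent from the other: a symmetric pseudometric, zero iff the orders
agree up to rotation/reflection, and complementary to the shared-adjacency
count (shared + distance = number of genes). Rearrangement *scenario*
reconstruction (common-interval / CREx-style inference) is deliberately
out of scope; conservation frequencies across a genome panel are reported
instead, leaving "hot spot" judgements to the user.

## Synthetic data

`make_mitogenome` emulates the features of scale-insect mitogenomes that
the analyses actually consume:

* **A+T target** (default 0.86, the regime of the most AT-rich insect
  mitogenomes). Sense-codon frequencies are drawn once per species from a
  Dirichlet whose base measure is exponentially tilted toward A/T-rich
  codons, with the tilt solved by bisection so the expected A+T equals
  the target; draws are rejected until the realised whole-genome A+T is
  within ±2% (targets above 0.95 are refused — start/stop codons impose
  a floor on G+C).
* **Codon bias strength** via the Dirichlet concentration α (default
  0.15, averaged over the 62 sense codons): smaller α gives sparser
  usage, hence lower ENC; α ∈ {1.0, 0.3, 0.1} spans weak to extreme bias.
* **Structure**: all 37 genes plus control region in the ancestral insect
  gene order, with `n_rearrangements` (default 2) random tRNA-block
  transpositions/inversions — rearrangements in these genomes
  concentrate in tRNA blocks; PCGs get proper ATN starts and TAA/TAG
  stops with no internal stops by construction; tRNAs are 50–66 nt
  (emulating D/T-arm-truncated tRNAs); the control region is 100–1400 bp
  and extra AT-rich; intergenic spacers are 0–30 bp. Gene lengths default
  to round figures near real mitochondrial genes (cox1 512 codons,
  atp8 53, nad4L 89, ...), keeping the short genes short so their Ka/Ks
  stays volatile, as observed in real data.
* **Determinism**: everything derives from (seed, index); the GenBank
  writer pins its date field so output is byte-stable.

What it does *not* emulate: phylogenetic correlation between species,
gene overlaps, indels within genes, secondary-structure-realistic tRNA or
rRNA sequences, and realistic within-genome heterogeneity of codon bias.
Consequently, passing tests demonstrate the correctness and calibration
of the statistics on data with the assumed structure, not the biological
conclusions one would draw from real genomes — in particular, Ka/Ks
between independently generated genomes sits near saturation and is used
only as a mechanics check, while calibrated recovery uses
`simulate_divergence`.

`simulate_divergence` diverges an ancestral CDS along two lineages:
candidate point mutations arrive as a Poisson number of events (uniform
over sites, split between lineages), accepted with probability
min(1, 1/ω) if synonymous and min(1, ω) if nonsynonymous — so the
nonsynonymous/synonymous rate ratio is ω for any ω > 0 — and always
rejected if they create a stop. The event count is calibrated so the
expected accepted synonymous divergence equals `target_dS` (computed from
the ancestor's one-step change spectrum); realised per-site counts are
returned as ground truth. Accepted-event counts include multiple hits at
a site, so realised divergence can slightly exceed what distance
estimators can see; Jukes–Cantor correction absorbs most of this at the
dS ≤ 0.3 used in the recovery experiments (3,000-codon pairs, 30
replicates per ω — sizes chosen to make the ω = 1 recovery band of ±15%
statistically comfortable while keeping the whole suite fast).

## Numerical and degenerate-input policy

Undefined quantities are NaN-flagged, never silently zeroed: skews with
empty base pairs, RSCU of absent families, ENC with no estimable 2- or
4-fold family, Ka/Ks of identical sequences, regression on constant x.
OLS requires n ≥ 3. The pipeline logs every skipped feature, ENC class
substitution and undefined ratio, counts them in `summary.json`, and
removes partial output directories on stage failure so a bundle is either
complete or absent.

## Known limitations

* Ka/Ks is count-based (NG86); for deep divergences or strong
  transition/transversion bias a codon-model method would differ.
* The neutrality partition inherits the usual caveat that the slope is a
  heuristic decomposition, not an estimate from a mechanistic model.
* Gene-order comparison reports adjacency statistics only; it cannot
  distinguish one large rearrangement from several small ones.
* The GenBank reader takes annotations as deposited; it does not rescue
  genes missed by upstream annotation.
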