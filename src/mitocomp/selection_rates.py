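"""Pairwise Ka/Ks per protein-coding gene via Nei-Gojobori counting.

Each species gene is aligned to the homologous gene of a designated
reference genome at the protein level (global Needleman-Wunsch, BLOSUM62,
affine gaps open -10 / extend -1), back-translated to codons, and run
through the Nei-Gojobori (1986) pathway-counting method with Jukes-Cantor
correction:

* potential sites per codon: 3 x the fraction of one-step nucleotide
  changes (changes producing stop codons excluded) that are synonymous,
  averaged over the two aligned codons — so N_sites + S_sites = 3 x the
  number of aligned non-gap codon pairs;
* observed differences for codons differing at k positions are averaged
  over all k! orderings of single steps, excluding orderings that pass
  through a stop codon;
* pN = Nd/N, pS = Sd/S, then d = -(3/4) ln(1 - (4/3) p).

Ka/Ks < 1 is read as purifying selection, = 1 as neutrality, > 1 as
positive selection.  The Ka/Ks ratio is undefined on identical sequences
(0/0) and flagged infinite when Ks = 0 with Ka > 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .codon_usage import GeneticCode, INVERTEBRATE_MITO
from .genes import PCGS
from .mito_io import MitogenomeRecord, extract_partition

logger = logging.getLogger("mitocomp")

GAP_CODON = "---"

#: tolerance used when comparing a Ka/Ks ratio to 1 for regime calls
NEUTRAL_TOL = 1e-9


@dataclass(frozen=True)
class CodonAlignment:
    """Two gap-aligned coding sequences, gaps in whole-codon units."""

    gene: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("aligned codon lists differ in length")

    @classmethod
    def from_ungapped(cls, gene: str, seq_a: str, seq_b: str) -> "CodonAlignment":
        """Alignment-free pairing of two equal-length in-frame CDSs."""
        if len(seq_a) != len(seq_b) or len(seq_a) % 3:
            raise ValueError("sequences must be equal length multiples of 3")
        a = tuple(seq_a[i : i + 3].upper() for i in range(0, len(seq_a), 3))
        b = tuple(seq_b[i : i + 3].upper() for i in range(0, len(seq_b), 3))
        return cls(gene, a, b)

    @property
    def n_pairs(self) -> int:
        """Aligned codon pairs with no gap on either side."""
        return sum(
            1
            for a, b in zip(self.codons_a, self.codons_b)
            if a != GAP_CODON and b != GAP_CODON
        )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def align_codons(
    seq_a: str,
    seq_b: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    gene: str = "",
) -> CodonAlignment:
    """Protein-guided global codon alignment of two CDSs.

    Trailing incomplete codons are dropped; internal stops are tolerated
    (translated as '*', penalised by the matrix, excluded downstream by the
    Nei-Gojobori counter).  The first optimal alignment reported by the
    deterministic dynamic program is used.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    cods_a = [seq_a[i : i + 3] for i in range(0, len(seq_a) - len(seq_a) % 3, 3)]
    cods_b = [seq_b[i : i + 3] for i in range(0, len(seq_b) - len(seq_b) % 3, 3)]
    # drop a terminal stop codon: it is not a site under the counting model
    for cods in (cods_a, cods_b):
        if cods and cods[-1] in code.stops:
            cods.pop()
    if not cods_a or not cods_b:
        raise ValueError("no complete codons to align")
    prot_a = "".join(
        "X" if "N" in c else ("*" if c in code.stops else code.forward[c])
        for c in cods_a
    )
    prot_b = "".join(
        "X" if "N" in c else ("*" if c in code.stops else code.forward[c])
        for c in cods_b
    )
    if "*" in prot_a or "*" in prot_b:
        logger.warning("internal stop codon(s) in %s; excluded from site counts",
                       gene or "alignment")

    alignment = _ALIGNER.align(prot_a, prot_b)[0]
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    blocks_a, blocks_b = alignment.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        while ia < a0:  # residues of A skipped -> gap in B
            out_a.append(cods_a[ia]); out_b.append(GAP_CODON); ia += 1
        while ib < b0:
            out_a.append(GAP_CODON); out_b.append(cods_b[ib]); ib += 1
        for k in range(a1 - a0):
            out_a.append(cods_a[a0 + k]); out_b.append(cods_b[b0 + k])
        ia, ib = a1, b1
    while ia < len(cods_a):
        out_a.append(cods_a[ia]); out_b.append(GAP_CODON); ia += 1
    while ib < len(cods_b):
        out_a.append(GAP_CODON); out_b.append(cods_b[ib]); ib += 1
    return CodonAlignment(gene, tuple(out_a), tuple(out_b))


# ---------------------------------------------------------------------------
# Nei-Gojobori tables (cached per genetic code)

_SITES_CACHE: dict[int, dict[str, float]] = {}
_PATHS_CACHE: dict[int, dict[tuple[str, str], tuple[float, float]]] = {}


def _syn_sites_table(code: GeneticCode) -> dict[str, float]:
    """Synonymous potential sites per sense codon (out of 3 total)."""
    if code.table_id in _SITES_CACHE:
        return _SITES_CACHE[code.table_id]
    table: dict[str, float] = {}
    for codon in code.sense_codons:
        syn = valid = 0
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1 :]
                if mutant in code.stops:
                    continue
                valid += 1
                if code.forward[mutant] == code.forward[codon]:
                    syn += 1
        table[codon] = 3.0 * syn / valid if valid else 0.0
    _SITES_CACHE[code.table_id] = table
    return table


def _step_type(c1: str, c2: str, code: GeneticCode) -> str:
    return "syn" if code.forward[c1] == code.forward[c2] else "nonsyn"


def _pair_differences(code: GeneticCode) -> dict[tuple[str, str], tuple[float, float]]:
    """(Nd, Sd) contribution for every ordered pair of distinct sense codons.

    Averaged over all orderings of the single-nucleotide steps from a to b
    that avoid stop-codon intermediates.  If every complete pathway is
    blocked, the pair falls back to averaging the per-position direct
    changes that are individually valid, scaled to the number of differing
    positions (logged; rare under real codes).
    """
    if code.table_id in _PATHS_CACHE:
        return _PATHS_CACHE[code.table_id]
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for a in code.sense_codons:
        for b in code.sense_codons:
            if a == b:
                continue
            diff = [i for i in range(3) if a[i] != b[i]]
            path_counts: list[tuple[int, int]] = []
            for order in itertools.permutations(diff):
                cur = a
                nd = sd = 0
                ok = True
                for pos in order:
                    nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                    if nxt in code.stops:
                        ok = False
                        break
                    if _step_type(cur, nxt, code) == "syn":
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
                if ok:
                    path_counts.append((nd, sd))
            if path_counts:
                nd = sum(p[0] for p in path_counts) / len(path_counts)
                sd = sum(p[1] for p in path_counts) / len(path_counts)
            else:
                # all pathways stop-blocked: average valid direct single steps
                logger.info("all pathways blocked for %s->%s; partial decomposition",
                            a, b)
                singles = []
                for pos in diff:
                    m1 = a[:pos] + b[pos] + a[pos + 1 :]
                    m2 = b[:pos] + a[pos] + b[pos + 1 :]
                    for base_codon, mutant in ((a, m1), (b, m2)):
                        if mutant not in code.stops:
                            singles.append(_step_type(base_codon, mutant, code))
                if singles:
                    frac_syn = sum(s == "syn" for s in singles) / len(singles)
                    sd = frac_syn * len(diff)
                    nd = (1 - frac_syn) * len(diff)
                else:
                    nd = sd = 0.0
            table[(a, b)] = (nd, sd)
    _PATHS_CACHE[code.table_id] = table
    return table


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - (4/3) p); NaN for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    gene: str
    n_codon_pairs: int
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float
    ratio: float  # NaN undefined, inf when Ks = 0 < Ka
    regime: str  # purifying | neutral | positive | undefined


def _classify(ka: float, ks: float) -> tuple[float, str]:
    if math.isnan(ka) or math.isnan(ks):
        return math.nan, "undefined"
    if ks == 0.0:
        if ka > 0.0:
            return math.inf, "positive"
        return math.nan, "undefined"
    ratio = ka / ks
    if abs(ratio - 1.0) <= NEUTRAL_TOL:
        return ratio, "neutral"
    return ratio, "purifying" if ratio < 1.0 else "positive"


def nei_gojobori(
    aln: CodonAlignment, code: GeneticCode = INVERTEBRATE_MITO
) -> KaKsResult:
    """Nei-Gojobori Ka/Ks with Jukes-Cantor correction for one alignment.

    Codon pairs containing a gap, an N, or a stop codon are excluded from
    the site and difference counts.  Symmetric in the two sequences.
    """
    sites = _syn_sites_table(code)
    paths = _pair_differences(code)
    n_pairs = 0
    s_sites = n_sites = 0.0
    nd = sd = 0.0
    for a, b in zip(aln.codons_a, aln.codons_b):
        if a == GAP_CODON or b == GAP_CODON or "N" in a or "N" in b:
            continue
        if a in code.stops or b in code.stops:
            continue
        n_pairs += 1
        s_codon = (sites[a] + sites[b]) / 2.0
        s_sites += s_codon
        n_sites += 3.0 - s_codon
        if a != b:
            d_nd, d_sd = paths[(a, b)]
            nd += d_nd
            sd += d_sd
    if n_pairs < 10:
        logger.warning("%s: only %d aligned codon pairs; Ka/Ks unstable",
                       aln.gene or "alignment", n_pairs)
    p_n = nd / n_sites if n_sites > 0 else math.nan
    p_s = sd / s_sites if s_sites > 0 else math.nan
    ka = jukes_cantor(p_n) if not math.isnan(p_n) else math.nan
    ks = jukes_cantor(p_s) if not math.isnan(p_s) else math.nan
    ratio, regime = _classify(ka, ks)
    return KaKsResult(
        gene=aln.gene, n_codon_pairs=n_pairs,
        N_sites=n_sites, S_sites=s_sites, Nd=nd, Sd=sd,
        pN=p_n, pS=p_s, Ka=ka, Ks=ks, ratio=ratio, regime=regime,
    )


def kaks_pair(
    seq_a: str,
    seq_b: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    gene: str = "",
) -> KaKsResult:
    """Align two CDSs and run Nei-Gojobori in one call."""
    return nei_gojobori(align_codons(seq_a, seq_b, code, gene=gene), code)


def _gene_cds(record: MitogenomeRecord, gene: str) -> str | None:
    for name, seq in extract_partition(record, "PCG"):
        if name == gene:
            return seq
    return None


def group_kaks(
    records: list[MitogenomeRecord],
    reference: MitogenomeRecord,
    genes: tuple[str, ...] = PCGS,
    code: GeneticCode = INVERTEBRATE_MITO,
    mean_mode: str = "mean_of_ratios",
) -> dict[str, dict]:
    """Per-gene Ka/Ks of every record against a reference genome.

    Returns ``{gene: {"results": [KaKsResult...], "mean_ratio": float,
    "n_defined": int, "n_undefined": int}}``.  ``mean_mode`` selects the
    per-gene summary: ``"mean_of_ratios"`` (default) averages the defined
    finite pairwise ratios; ``"ratio_of_means"`` divides mean Ka by mean Ks.
    """
    if mean_mode not in {"mean_of_ratios", "ratio_of_means"}:
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    out: dict[str, dict] = {}
    for gene in genes:
        ref_cds = _gene_cds(reference, gene)
        if ref_cds is None:
            raise ValueError(f"reference {reference.id} lacks gene {gene}")
        results = []
        for rec in records:
            cds = _gene_cds(rec, gene)
            if cds is None:
                logger.warning("%s: gene %s missing, skipped", rec.id, gene)
                continue
            results.append(kaks_pair(cds, ref_cds, code, gene=gene))
        finite = [r.ratio for r in results
                  if not math.isnan(r.ratio) and not math.isinf(r.ratio)]
        if mean_mode == "mean_of_ratios":
            mean_ratio = sum(finite) / len(finite) if finite else math.nan
        else:
            kas = [r.Ka for r in results if not math.isnan(r.Ka)]
            kss = [r.Ks for r in results if not math.isnan(r.Ks)]
            mean_ratio = (
                sum(kas) / len(kas) / (sum(kss) / len(kss))
                if kas and kss and sum(kss) > 0 else math.nan
            )
        out[gene] = {
            "results": results,
            "mean_ratio": mean_ratio,
            "n_defined": len(finite),
            "n_undefined": len(results) - len(finite),
        }
    return out


def classify_ratio(ratio: float) -> str:
    """Selection regime of a Ka/Ks value: <1 purifying, =1 neutral, >1 positive."""
    if math.isnan(ratio):
        return "undefined"
    if math.isinf(ratio):
        return "positive"
    if abs(ratio - 1.0) <= NEUTRAL_TOL:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "align_codons",
    "nei_gojobori",
    "kaks_pair",
    "group_kaks",
    "classify_ratio",
    "jukes_cantor",
    "GAP_CODON",
    "NEUTRAL_TOL",
]
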