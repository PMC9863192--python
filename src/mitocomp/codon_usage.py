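"""Codon usage statistics under the invertebrate mitochondrial genetic code.

Implements the classic codon-bias toolkit for mitochondrial protein-coding
genes:

* codon counting in frame 0 with stop exclusion and incomplete-codon
  handling (mitochondrial CDSs commonly end in a truncated ``T``/``TA``
  stop completed by polyadenylation);
* relative synonymous codon usage (RSCU) with the conventional
  over-/under-representation thresholds 1.6 and 0.6 (strict inequalities);
* G+C fractions by codon position (GC1/GC2/GC3, GC12 = mean of GC1 and GC2);
* Wright's effective number of codons (ENC) and its expected-under-mutation
  curve ENC*(s) = 2 + s + 29/(s^2 + (1-s)^2).

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial: TGA=Trp, AGA/AGG=Ser, ATA=Met; stops TAA/TAG), giving 62
sense codons whose synonymous families partition into twelve 2-fold and six
4-fold families plus 6-fold Leu and 8-fold Ser.  ENC degeneracy classes are
derived from the active code's true family sizes, so under table 5 the
no-bias limit is 62 rather than the familiar 61 of the standard code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from Bio.Data import CodonTable

logger = logging.getLogger("mitocomp")

_CODE_CACHE: dict[int, "GeneticCode"] = {}

BASES = "TCAG"
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table plus its synonymous-family structure."""

    table_id: int
    forward: dict[str, str]  # sense codon -> one-letter amino acid
    stops: frozenset[str]

    @classmethod
    def from_ncbi(cls, table_id: int = 5) -> "GeneticCode":
        if table_id not in _CODE_CACHE:
            t = CodonTable.unambiguous_dna_by_id[table_id]
            _CODE_CACHE[table_id] = cls(
                table_id=table_id,
                forward=dict(t.forward_table),
                stops=frozenset(t.stop_codons),
            )
        return _CODE_CACHE[table_id]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c in self.forward)

    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families: amino acid -> its codons (in TCAG order)."""
        fam: dict[str, list[str]] = {}
        for c in self.sense_codons:
            fam.setdefault(self.forward[c], []).append(c)
        return {aa: tuple(cods) for aa, cods in fam.items()}

    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Family size -> amino acids in that class (code-aware, not templated)."""
        classes: dict[int, list[str]] = {}
        for aa, cods in self.families().items():
            classes.setdefault(len(cods), []).append(aa)
        return {k: tuple(v) for k, v in sorted(classes.items())}

    def translate(self, cds: str) -> str:
        """Protein translation; stops as '*', codons with N as 'X'."""
        out = []
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3]
            if "N" in codon:
                out.append("X")
            elif codon in self.stops:
                out.append("*")
            else:
                out.append(self.forward[codon])
        return "".join(out)


INVERTEBRATE_MITO = GeneticCode.from_ncbi(5)


@dataclass
class CodonUsageSummary:
    """Codon counts and derived statistics for a set of coding sequences."""

    codon_counts: dict[str, int]  # sense codons only
    stop_counts: dict[str, int]
    n_codons: int
    code: GeneticCode = field(default_factory=lambda: INVERTEBRATE_MITO)

    def count(self, codon: str) -> int:
        return self.codon_counts.get(codon, 0)

    def aa_usage(self) -> dict[str, int]:
        usage: dict[str, int] = {}
        for aa, cods in self.code.families().items():
            usage[aa] = sum(self.count(c) for c in cods)
        return usage


def count_codons(
    cds_list: list[str], code: GeneticCode = INVERTEBRATE_MITO
) -> CodonUsageSummary:
    """Count codons of each CDS in frame from position 1.

    Trailing incomplete codons (1-2 nt, truncated stops) are dropped; stop
    codons are tallied separately and excluded from ``n_codons``; codons
    containing N are skipped.  An internal (non-final) stop codon triggers a
    warning naming the sequence index and codon position.
    """
    counts: dict[str, int] = {}
    stop_counts: dict[str, int] = {}
    for gi, cds in enumerate(cds_list):
        cds = cds.upper()
        if len(cds) < 3:
            raise ValueError(f"sequence {gi} shorter than one codon")
        n_full = len(cds) // 3
        for ci in range(n_full):
            codon = cds[3 * ci : 3 * ci + 3]
            if "N" in codon:
                continue
            if codon in code.stops:
                stop_counts[codon] = stop_counts.get(codon, 0) + 1
                if ci != n_full - 1:
                    logger.warning(
                        "internal stop codon %s in sequence %d at codon %d",
                        codon, gi, ci + 1,
                    )
            else:
                counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageSummary(
        codon_counts=counts,
        stop_counts=stop_counts,
        n_codons=sum(counts.values()),
        code=code,
    )


def rscu(summary: CodonUsageSummary) -> dict[str, float]:
    """RSCU(c) = observed(c) / (family mean); NaN for codons of absent families.

    Within a family whose total count is positive the values sum exactly to
    the family size; an unused codon of a present family scores 0.
    """
    out: dict[str, float] = {}
    for aa, cods in summary.code.families().items():
        total = sum(summary.count(c) for c in cods)
        if total == 0:
            for c in cods:
                out[c] = math.nan
        else:
            expected = total / len(cods)
            for c in cods:
                out[c] = summary.count(c) / expected
    return out


#: Conventional RSCU thresholds (strict inequalities).
RSCU_OVER = 1.6
RSCU_UNDER = 0.6


def classify_rscu(
    summary: CodonUsageSummary,
    over: float = RSCU_OVER,
    under: float = RSCU_UNDER,
) -> dict[str, str]:
    """Per-codon class: overrepresented / underrepresented / unused / neutral.

    ``unused`` means count 0 within a family that is itself used; codons of
    entirely absent families are labelled ``absent``.  Thresholds are strict
    (RSCU exactly 1.6 or 0.6 is neutral).
    """
    values = rscu(summary)
    classes: dict[str, str] = {}
    for codon, v in values.items():
        if math.isnan(v):
            classes[codon] = "absent"
        elif summary.count(codon) == 0:
            classes[codon] = "unused"
        elif v > over:
            classes[codon] = "overrepresented"
        elif v < under:
            classes[codon] = "underrepresented"
        else:
            classes[codon] = "neutral"
    return classes


def rscu_class_report(summary: CodonUsageSummary) -> dict[str, dict[str, float]]:
    """Counts and mean RSCU per RSCU class (the headline Fig.-5-style numbers)."""
    values = rscu(summary)
    classes = classify_rscu(summary)
    report: dict[str, dict[str, float]] = {}
    for cls in ("overrepresented", "underrepresented", "unused", "neutral"):
        members = [c for c, k in classes.items() if k == cls]
        report[cls] = {
            "count": len(members),
            "mean_rscu": (
                sum(values[c] for c in members) / len(members) if members else math.nan
            ),
        }
    return report


def gc_positions(summary: CodonUsageSummary) -> tuple[float, float, float, float]:
    """(gc1, gc2, gc3, gc12) over sense codons; all amino acids included."""
    n = summary.n_codons
    if n == 0:
        return (math.nan,) * 4
    gc = [0, 0, 0]
    for codon, cnt in summary.codon_counts.items():
        for pos in range(3):
            if codon[pos] in "GC":
                gc[pos] += cnt
    gc1, gc2, gc3 = (g / n for g in gc)
    return gc1, gc2, gc3, (gc1 + gc2) / 2


def _family_F_hat(counts: list[int]) -> float | None:
    """Wright's homozygosity estimator F for one synonymous family.

    Defined for family total n >= 2: F = (n * sum(p_i^2) - 1) / (n - 1).
    Returns None when inestimable (n < 2).
    """
    n = sum(counts)
    if n < 2:
        return None
    p2 = sum((c / n) ** 2 for c in counts)
    return (n * p2 - 1.0) / (n - 1.0)


def enc(summary: CodonUsageSummary) -> float:
    """Wright's effective number of codons for a codon count table.

    ENC = sum over degeneracy classes c of K_c / Fbar_c, with K_c the number
    of amino acids in the class and Fbar_c the mean of the estimable,
    positive F values in the class.  Under the invertebrate mitochondrial
    code the classes are {2-fold x12, 4-fold x6, 6-fold Leu, 8-fold Ser} and
    20 = 12 + 6 + 1 + 1 is the exact single-codon-per-amino-acid floor.

    A class with no eligible family is interpolated from the 4-fold class
    when possible (logged); if the 2- or 4-fold class itself is empty the
    estimate is undefined (NaN).  The result is clipped to
    [20, number of sense codons].
    """
    code = summary.code
    families = code.families()
    classes = code.degeneracy_classes()

    f_bar: dict[int, float] = {}
    for size, aas in classes.items():
        if size == 1:  # non-degenerate amino acids contribute K_c / 1
            f_bar[size] = 1.0
            continue
        fs = []
        for aa in aas:
            f = _family_F_hat([summary.count(c) for c in families[aa]])
            if f is not None and f > 0:
                fs.append(f)
        if fs:
            f_bar[size] = sum(fs) / len(fs)

    for size in classes:
        if size not in f_bar:
            if size > 4 and 4 in f_bar:
                logger.info("ENC: class %d-fold empty, substituting 4-fold mean", size)
                f_bar[size] = f_bar[4]
            else:
                logger.warning("ENC undefined: no eligible family in %d-fold class", size)
                return math.nan

    value = sum(len(classes[size]) / f_bar[size] for size in classes)
    return float(min(max(value, 20.0), len(code.sense_codons)))


def enc_expected(gc3: float) -> float:
    """Expected ENC under pure mutation pressure at third-position G+C = s.

    Wright's curve ENC*(s) = 2 + s + 29 / (s^2 + (1-s)^2), continuous on
    [0, 1] with ENC*(0) = 31 and ENC*(1) = 32, maximal at s = 0.5.
    """
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError("GC3 must lie in [0, 1]")
    return 2.0 + gc3 + 29.0 / (gc3 ** 2 + (1.0 - gc3) ** 2)


def summarize_cds_set(
    cds_list: list[str], code: GeneticCode = INVERTEBRATE_MITO
) -> dict[str, float]:
    """One-stop summary (n_codons, gc1..gc3, gc12, enc) for a CDS pool."""
    s = count_codons(cds_list, code)
    gc1, gc2, gc3, gc12 = gc_positions(s)
    return {
        "n_codons": s.n_codons,
        "gc1": gc1, "gc2": gc2, "gc3": gc3, "gc12": gc12,
        "enc": enc(s),
    }


__all__ = [
    "ALL_CODONS",
    "GeneticCode",
    "INVERTEBRATE_MITO",
    "CodonUsageSummary",
    "count_codons",
    "rscu",
    "classify_rscu",
    "rscu_class_report",
    "gc_positions",
    "enc",
    "enc_expected",
    "summarize_cds_set",
    "RSCU_OVER",
    "RSCU_UNDER",
]
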