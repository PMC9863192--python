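"""Synthetic annotated mitogenomes and divergent CDS pairs.

The generator emulates the statistical structure of scale-insect (Coccidae)
mitogenomes so every analysis stage is testable offline: ~86% A+T content,
strong codon bias (species-level codon frequencies drawn from a sparse
Dirichlet tilted toward A/T-rich codons), 37 canonical genes in the
ancestral insect gene order with optional tRNA-block rearrangements,
truncated tRNAs (50-66 nt), and a control region of widely variable length.
Base composition is slightly A- and C-rich on the majority strand,
mirroring the positive AT skew / negative GC skew typical of these genomes.

``simulate_divergence`` produces CDS pairs diverged under a per-site
mutation process with a known nonsynonymous/synonymous acceptance ratio
(omega), providing ground truth for Ka/Ks parameter-recovery experiments.

Everything is deterministic under (seed, index).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .codon_usage import GeneticCode, INVERTEBRATE_MITO
from .genes import KIND_OF, YAKUBA_ORDER
from .mito_io import GeneFeature, MitogenomeRecord, revcomp, write_genbank

logger = logging.getLogger("mitocomp")

#: Default gene lengths in codons, near real insect mitochondrial genes;
#: nad4L and atp8 stay short so their Ka/Ks remains volatile, as observed.
DEFAULT_PCG_CODONS: dict[str, int] = {
    "cox1": 512, "cox2": 227, "cox3": 262, "cytb": 378,
    "nad1": 312, "nad2": 324, "nad3": 117, "nad4": 446,
    "nad4L": 89, "nad5": 572, "nad6": 174, "atp6": 224, "atp8": 53,
}

RRNA_LEN_RANGE: dict[str, tuple[int, int]] = {"rrnL": (1100, 1300), "rrnS": (650, 800)}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters for mitogenome generation."""

    seed: int = 0
    n_species: int = 5
    at_target: float = 0.86
    codon_dirichlet_alpha: float = 0.15
    gene_order_source: tuple[tuple[str, int], ...] = YAKUBA_ORDER
    n_rearrangements: int = 2
    trna_len_range: tuple[int, int] = (50, 66)
    cr_len_range: tuple[int, int] = (100, 1400)
    spacer_len_range: tuple[int, int] = (0, 30)
    pcg_len_table: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PCG_CODONS)
    )
    at_tolerance: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.at_target < 1.0:
            raise ValueError("at_target must be in (0, 1)")
        if self.at_target > 0.95:
            raise ValueError("at_target > 0.95 is infeasible with proper start/stop codons")
        if self.n_rearrangements < 0:
            raise ValueError("n_rearrangements must be >= 0")


@dataclass(frozen=True)
class DivergenceSpec:
    """Parameters for a simulated pair of diverged CDSs."""

    seed: int = 0
    n_codons: int = 300
    omega: float = 0.5
    target_dS: float = 0.2
    code: GeneticCode = INVERTEBRATE_MITO

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if not 0.0 < self.target_dS < 0.7:
            raise ValueError("target_dS must be in (0, 0.7)")


def _at_fraction(codon: str) -> float:
    return sum(b in "AT" for b in codon) / 3.0


def _tilted_codon_measure(code: GeneticCode, at_target: float) -> np.ndarray:
    """Base measure over sense codons with expected A+T equal to at_target.

    Exponential tilt m_c \\propto exp(beta * n_AT(c)); beta solved by
    bisection (the expected A+T fraction is monotone in beta).
    """
    codons = code.sense_codons
    at = np.array([_at_fraction(c) for c in codons])

    def expected_at(beta: float) -> float:
        w = np.exp(beta * 3 * at)
        w /= w.sum()
        return float((w * at).sum())

    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if expected_at(mid) < at_target:
            lo = mid
        else:
            hi = mid
    beta = (lo + hi) / 2.0
    w = np.exp(beta * 3 * at)
    return w / w.sum()


def _base_probs(at: float) -> np.ndarray:
    """Majority-strand base probabilities (A, C, G, T): A- and C-rich."""
    at = min(max(at, 0.02), 0.98)
    gc = 1.0 - at
    return np.array([0.55 * at, 0.60 * gc, 0.40 * gc, 0.45 * at])


def _random_seq(rng: np.random.Generator, n: int, at: float) -> str:
    bases = np.array(list("ACGT"))
    return "".join(rng.choice(bases, size=n, p=_base_probs(at)))


def _trna_blocks(order: list[tuple[str, int]]) -> list[tuple[int, int]]:
    """Maximal runs [i, j) of consecutive tRNA genes in a linear order."""
    blocks = []
    i = 0
    n = len(order)
    while i < n:
        if KIND_OF.get(order[i][0]) == "tRNA":
            j = i
            while j < n and KIND_OF.get(order[j][0]) == "tRNA":
                j += 1
            blocks.append((i, j))
            i = j
        else:
            i += 1
    return blocks


def rearranged_order(
    source: tuple[tuple[str, int], ...],
    n_rearrangements: int,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Apply random tRNA-block transpositions/inversions to a gene order."""
    order = list(source)
    for _ in range(n_rearrangements):
        blocks = _trna_blocks(order)
        if not blocks:
            break
        i, j = blocks[rng.integers(len(blocks))]
        # choose a sub-block of 1..(j-i) consecutive tRNAs
        k = int(rng.integers(i, j))
        m = int(rng.integers(k + 1, j + 1))
        block = order[k:m]
        if rng.random() < 0.5:
            # in-place inversion (reverse and flip strands)
            order[k:m] = [(g, -s) for g, s in reversed(block)]
        else:
            rest = order[:k] + order[m:]
            pos = int(rng.integers(len(rest) + 1))
            order = rest[:pos] + block + rest[pos:]
    return order


def _sample_pcg(
    rng: np.random.Generator,
    n_codons: int,
    probs: np.ndarray,
    code: GeneticCode,
) -> str:
    """One PCG: ATN start, sense-codon interior (no internal stops), TAA/TAG stop."""
    codons = list(code.sense_codons)
    starts = [c for c in codons if c.startswith("AT")]
    p_start = np.array([probs[codons.index(c)] for c in starts])
    p_start /= p_start.sum()
    start = rng.choice(starts, p=p_start)
    interior = rng.choice(codons, size=max(n_codons - 2, 0), p=probs)
    stop = "TAA" if rng.random() < 0.9 else "TAG"
    return start + "".join(interior) + stop


def make_mitogenome(
    spec: SyntheticSpec,
    index: int = 0,
    path=None,
    max_tries: int = 60,
) -> MitogenomeRecord:
    """Generate one annotated synthetic mitogenome (optionally as GenBank).

    Species-level codon frequencies are drawn from a Dirichlet with
    concentration ``codon_dirichlet_alpha`` around an A/T-tilted base
    measure; draws are repeated until the realised whole-genome A+T falls
    within ``at_tolerance`` of ``at_target``.  Deterministic under
    ``(spec.seed, index)``.
    """
    rng = np.random.default_rng([int(spec.seed), int(index)])
    code = INVERTEBRATE_MITO
    measure = _tilted_codon_measure(code, spec.at_target)
    alpha_vec = spec.codon_dirichlet_alpha * len(measure) * measure

    order = rearranged_order(spec.gene_order_source, spec.n_rearrangements, rng)

    record = None
    for attempt in range(max_tries):
        probs = rng.dirichlet(alpha_vec)
        parts: list[str] = []
        features: list[GeneFeature] = []
        pos = 1  # next free coordinate, 1-based
        for gene, sign in order:
            kind = KIND_OF.get(gene, "CR")
            if kind == "PCG":
                coding = _sample_pcg(rng, spec.pcg_len_table[gene], probs, code)
            elif kind == "tRNA":
                n = int(rng.integers(spec.trna_len_range[0], spec.trna_len_range[1] + 1))
                coding = _random_seq(rng, n, min(spec.at_target + 0.03, 0.97))
            elif kind == "rRNA":
                lo, hi = RRNA_LEN_RANGE[gene]
                coding = _random_seq(rng, int(rng.integers(lo, hi + 1)), spec.at_target)
            else:  # control region: long, extremely A+T rich
                n = int(rng.integers(spec.cr_len_range[0], spec.cr_len_range[1] + 1))
                coding = _random_seq(rng, n, min(spec.at_target + 0.05, 0.97))
            placed = revcomp(coding) if sign < 0 else coding
            start = pos
            end = pos + len(placed) - 1
            features.append(
                GeneFeature(
                    canonical_name=gene,
                    kind=kind,
                    start=start,
                    end=end,
                    strand=None if kind == "CR" else ("-" if sign < 0 else "+"),
                )
            )
            parts.append(placed)
            pos = end + 1
            spacer = int(rng.integers(spec.spacer_len_range[0],
                                      spec.spacer_len_range[1] + 1))
            if spacer:
                parts.append(_random_seq(rng, spacer, spec.at_target))
                pos += spacer
        genome = "".join(parts)
        at = (genome.count("A") + genome.count("T")) / len(genome)
        if abs(at - spec.at_target) <= spec.at_tolerance:
            record = MitogenomeRecord(
                id=f"SYN{spec.seed:04d}.{index}",
                organism=f"Synthetica coccida {index}",
                sequence=genome,
                features=features,
            )
            break
    if record is None:
        raise RuntimeError(
            f"could not realise A+T {spec.at_target:.2f} +/- {spec.at_tolerance:.2f} "
            f"in {max_tries} draws"
        )
    if path is not None:
        write_genbank(record, path)
    return record


def make_mitogenome_set(spec: SyntheticSpec) -> list[MitogenomeRecord]:
    """``spec.n_species`` genomes under one spec (indices 0..n-1)."""
    return [make_mitogenome(spec, i) for i in range(spec.n_species)]


def random_cds(
    rng: np.random.Generator,
    n_codons: int,
    code: GeneticCode = INVERTEBRATE_MITO,
    at_target: float = 0.7,
) -> str:
    """A random in-frame CDS over sense codons (mildly A/T tilted)."""
    measure = _tilted_codon_measure(code, at_target)
    return "".join(rng.choice(code.sense_codons, size=n_codons, p=measure))


def simulate_divergence(
    dspec: DivergenceSpec,
    ancestral: str | None = None,
) -> tuple[str, str, float, float]:
    """Diverge an ancestral CDS into a pair with known omega.

    Candidate point mutations arrive as a Poisson number of events placed
    uniformly over sites and split between the two lineages.  A candidate
    is accepted with probability min(1, 1/omega) if synonymous and
    min(1, omega) if nonsynonymous; mutations creating stop codons are
    always rejected.  Returns ``(seq_a, seq_b, realized_dS, realized_dN)``
    where the realised rates are accepted substitutions per Nei-Gojobori
    potential site of the ancestor (ground truth for recovery tests).
    """
    code = dspec.code
    rng = np.random.default_rng([int(dspec.seed), 91])
    if ancestral is None:
        ancestral = random_cds(rng, dspec.n_codons, code)
    if len(ancestral) % 3:
        raise ValueError("ancestral CDS length must be a multiple of 3")

    from .selection_rates import _syn_sites_table

    sites = _syn_sites_table(code)
    anc_codons = [ancestral[i : i + 3] for i in range(0, len(ancestral), 3)]
    if any(c in code.stops for c in anc_codons):
        raise ValueError("ancestral CDS contains stop codons")
    s_sites = sum(sites[c] for c in anc_codons)
    n_sites = 3.0 * len(anc_codons) - s_sites

    # Calibrate the number of candidate events so the expected accepted
    # synonymous count is target_dS * S_sites.
    syn_changes = tostop = total = 0
    for c in anc_codons:
        for p in range(3):
            for b in "ACGT":
                if b == c[p]:
                    continue
                m = c[:p] + b + c[p + 1 :]
                total += 1
                if m in code.stops:
                    tostop += 1
                elif code.forward[m] == code.forward[c]:
                    syn_changes += 1
    p_syn_accept = (syn_changes / total) * min(1.0, 1.0 / dspec.omega)
    n_events = rng.poisson(dspec.target_dS * s_sites / p_syn_accept)

    lineages = [list(anc_codons), list(anc_codons)]
    accepted_syn = accepted_nonsyn = 0
    acc_syn = min(1.0, 1.0 / dspec.omega)
    acc_non = min(1.0, dspec.omega)
    for _ in range(n_events):
        lin = lineages[int(rng.integers(2))]
        ci = int(rng.integers(len(lin)))
        p = int(rng.integers(3))
        codon = lin[ci]
        alternatives = [x for x in "ACGT" if x != codon[p]]
        b = alternatives[int(rng.integers(3))]
        mutant = codon[:p] + b + codon[p + 1 :]
        if mutant in code.stops:
            continue
        syn = code.forward[mutant] == code.forward[codon]
        if rng.random() < (acc_syn if syn else acc_non):
            lin[ci] = mutant
            if syn:
                accepted_syn += 1
            else:
                accepted_nonsyn += 1
    seq_a = "".join(lineages[0])
    seq_b = "".join(lineages[1])
    realized_ds = accepted_syn / s_sites if s_sites else math.nan
    realized_dn = accepted_nonsyn / n_sites if n_sites else math.nan
    return seq_a, seq_b, realized_ds, realized_dn


__all__ = [
    "SyntheticSpec",
    "DivergenceSpec",
    "make_mitogenome",
    "make_mitogenome_set",
    "simulate_divergence",
    "random_cds",
    "rearranged_order",
    "DEFAULT_PCG_CODONS",
]
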