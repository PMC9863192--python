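"""Codon alignment and Nei-Gojobori Ka/Ks behaviour."""

import math

import numpy as np
import pytest

from mitocomp.codon_usage import INVERTEBRATE_MITO
from mitocomp.selection_rates import (
    CodonAlignment,
    align_codons,
    classify_ratio,
    group_kaks,
    jukes_cantor,
    kaks_pair,
    nei_gojobori,
)
from mitocomp.synthetic_data import (
    DivergenceSpec,
    SyntheticSpec,
    make_mitogenome,
    random_cds,
    simulate_divergence,
)

CODE = INVERTEBRATE_MITO


def _gotoh_score(a: str, b: str, matrix, open_=-10.0, ext=-1.0) -> float:
    """Independent affine-gap global alignment score (plain Gotoh DP)."""
    NEG = float("-inf")
    m, n = len(a), len(b)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (consume a)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = open_ + (i - 1) * ext
    for j in range(1, n + 1):
        Y[0][j] = open_ + (j - 1) * ext
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext, X[i][j - 1] + open_)
    return max(M[m][n], X[m][n], Y[m][n])


class TestAlignCodons:
    def test_identical_sequences_gapless(self):
        seq = "ATGTTTGGACAT"
        aln = align_codons(seq, seq)
        assert aln.codons_a == aln.codons_b
        assert "---" not in aln.codons_a

    def test_single_codon_insertion(self):
        aln = align_codons("ATGTTT", "ATGGCTTTT")
        assert len(aln.codons_a) == 3  # 9 nt alignment
        assert aln.codons_a.count("---") == 1
        assert "".join(c for c in aln.codons_a if c != "---") == "ATGTTT"
        assert "".join(aln.codons_b) == "ATGGCTTTT"

    def test_score_matches_independent_gotoh(self, rng):
        from Bio.Align import substitution_matrices

        from mitocomp.selection_rates import _ALIGNER

        matrix = substitution_matrices.load("BLOSUM62")
        for _ in range(5):
            a = random_cds(rng, int(rng.integers(20, 60)), CODE)
            b = random_cds(rng, int(rng.integers(20, 60)), CODE)
            pa, pb = CODE.translate(a), CODE.translate(b)
            assert _ALIGNER.score(pa, pb) == pytest.approx(
                _gotoh_score(pa, pb, matrix)
            )

    def test_terminal_stop_dropped(self):
        aln = align_codons("ATGTTTTAA", "ATGTTT")
        assert len(aln.codons_a) == 2

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_codons("", "ATG")


class TestNeiGojobori:
    def test_identical_sequences_undefined_ratio(self):
        seq = "ATGTTTGGACATCCA" * 5
        r = kaks_pair(seq, seq)
        assert r.Ka == 0.0 and r.Ks == 0.0
        assert math.isnan(r.ratio)
        assert r.regime == "undefined"

    def test_single_synonymous_difference_hand_count(self):
        a = "TTT" * 100
        b = "TTT" * 50 + "TTC" + "TTT" * 49
        r = nei_gojobori(CodonAlignment.from_ungapped("phe", a, b))
        assert r.Sd == pytest.approx(1.0)
        assert r.Nd == pytest.approx(0.0)
        assert r.Ka == pytest.approx(0.0)
        assert r.Ks > 0
        assert r.regime == "purifying"

    def test_site_conservation(self, rng):
        for _ in range(5):
            anc = random_cds(rng, 200, CODE)
            sa, sb, _, _ = simulate_divergence(
                DivergenceSpec(seed=int(rng.integers(1000)), omega=0.8), anc
            )
            r = nei_gojobori(CodonAlignment.from_ungapped("x", sa, sb))
            assert r.N_sites + r.S_sites == pytest.approx(3 * r.n_codon_pairs, abs=1e-9)

    def test_swap_invariance(self, rng):
        anc = random_cds(rng, 150, CODE)
        sa, sb, _, _ = simulate_divergence(DivergenceSpec(seed=3, omega=1.2), anc)
        r1 = nei_gojobori(CodonAlignment.from_ungapped("x", sa, sb))
        r2 = nei_gojobori(CodonAlignment.from_ungapped("x", sb, sa))
        assert r1.Ka == pytest.approx(r2.Ka, abs=1e-12)
        assert r1.Ks == pytest.approx(r2.Ks, abs=1e-12)

    def test_gap_and_stop_codons_excluded(self):
        aln = CodonAlignment("g", ("ATG", "---", "TAA", "TTT"),
                             ("ATG", "CCC", "TGG", "TTC"))
        r = nei_gojobori(aln)
        assert r.n_codon_pairs == 2  # gap pair and stop pair dropped

    def test_neutral_omega_recovery(self):
        ratios = []
        for rep in range(12):
            sa, sb, _, _ = simulate_divergence(
                DivergenceSpec(seed=rep, n_codons=300, omega=1.0, target_dS=0.2)
            )
            r = nei_gojobori(CodonAlignment.from_ungapped("x", sa, sb))
            if math.isfinite(r.ratio):
                ratios.append(r.ratio)
        assert 0.85 <= float(np.mean(ratios)) <= 1.15

    def test_omega_half_recovery(self):
        ratios = []
        for rep in range(10):
            sa, sb, _, _ = simulate_divergence(
                DivergenceSpec(seed=100 + rep, n_codons=300, omega=0.5, target_dS=0.3)
            )
            r = nei_gojobori(CodonAlignment.from_ungapped("x", sa, sb))
            ratios.append(r.ratio)
        assert abs(float(np.mean(ratios)) - 0.5) <= 0.15

    def test_jukes_cantor_saturation_flagged(self):
        assert math.isnan(jukes_cantor(0.76))
        assert jukes_cantor(0.0) == 0.0


class TestClassification:
    @pytest.mark.parametrize(
        "ratio,regime",
        [(0.47, "purifying"), (1.0, "neutral"), (3.20, "positive"),
         (math.inf, "positive"), (math.nan, "undefined")],
    )
    def test_regimes(self, ratio, regime):
        assert classify_ratio(ratio) == regime


@pytest.fixture(scope="module")
def reference():
    return make_mitogenome(SyntheticSpec(seed=21, n_rearrangements=0), 0)


class TestGroupKaks:
    def test_reference_vs_itself_all_undefined(self, reference):
        res = group_kaks([reference], reference, genes=("cox1", "atp8"))
        for gene in ("cox1", "atp8"):
            assert res[gene]["n_defined"] == 0
            assert math.isnan(res[gene]["mean_ratio"])

    def test_gene_specific_omega_straddles_one(self):
        """Genes simulated under purifying vs positive selection separate."""
        rng = np.random.default_rng(9)
        genes = {"conserved": 0.2, "adaptive": 1.5}
        means = {}
        for gene, omega in genes.items():
            anc = random_cds(rng, 250, CODE)
            ratios = []
            for rep in range(5):
                sa, sb, _, _ = simulate_divergence(
                    DivergenceSpec(seed=rep + 500, omega=omega, target_dS=0.25), anc
                )
                r = nei_gojobori(CodonAlignment.from_ungapped(gene, sa, sb))
                if math.isfinite(r.ratio):
                    ratios.append(r.ratio)
            means[gene] = float(np.mean(ratios))
        assert means["conserved"] < 1.0 < means["adaptive"]

    def test_missing_gene_skipped(self, reference):
        from mitocomp.mito_io import MitogenomeRecord

        no_genes = MitogenomeRecord("empty", "E", "ACGT" * 500, [])
        res = group_kaks([no_genes], reference, genes=("cox1",))
        assert res["cox1"]["results"] == []

    def test_mean_modes(self, reference, rng):
        rec = make_mitogenome(SyntheticSpec(seed=22, n_rearrangements=0), 0)
        r1 = group_kaks([rec], reference, genes=("nad3",), mean_mode="mean_of_ratios")
        r2 = group_kaks([rec], reference, genes=("nad3",), mean_mode="ratio_of_means")
        assert math.isfinite(r1["nad3"]["mean_ratio"])
        assert math.isfinite(r2["nad3"]["mean_ratio"])
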