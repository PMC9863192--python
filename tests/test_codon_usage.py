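"""Codon counting, RSCU, positional GC and Wright's ENC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.codon_usage import (
    ALL_CODONS,
    GeneticCode,
    INVERTEBRATE_MITO,
    CodonUsageSummary,
    classify_rscu,
    count_codons,
    enc,
    enc_expected,
    gc_positions,
    rscu,
)

CODE = INVERTEBRATE_MITO


class TestGeneticCode:
    def test_invertebrate_mito_has_62_sense_codons(self):
        assert len(CODE.sense_codons) == 62
        assert CODE.stops == frozenset({"TAA", "TAG"})

    def test_reassigned_codons(self):
        assert CODE.forward["TGA"] == "W"
        assert CODE.forward["AGA"] == "S"
        assert CODE.forward["AGG"] == "S"
        assert CODE.forward["ATA"] == "M"

    def test_degeneracy_classes(self):
        classes = CODE.degeneracy_classes()
        assert {size: len(aas) for size, aas in classes.items()} == {
            2: 12, 4: 6, 6: 1, 8: 1,
        }
        assert classes[8] == ("S",)
        assert classes[6] == ("L",)

    def test_families_partition_sense_codons(self):
        fams = CODE.families()
        codons = [c for cods in fams.values() for c in cods]
        assert sorted(codons) == sorted(CODE.sense_codons)


class TestCountCodons:
    def test_stop_excluded(self):
        s = count_codons(["ATGTTTTAA"], CODE)
        assert s.codon_counts == {"ATG": 1, "TTT": 1}
        assert s.n_codons == 2
        assert s.stop_counts == {"TAA": 1}

    def test_dangling_base_dropped(self):
        s = count_codons(["ATGTTTT"], CODE)
        assert s.codon_counts == {"ATG": 1, "TTT": 1}

    def test_codons_with_n_skipped(self):
        s = count_codons(["ATGNNNTTT"], CODE)
        assert s.n_codons == 2

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            count_codons(["AT"], CODE)

    def test_matches_three_mer_stepper_oracle(self, rng):
        cds = "".join(rng.choice(CODE.sense_codons, size=500))
        s = count_codons([cds], CODE)
        oracle: dict = {}
        for i in range(0, len(cds), 3):  # frame-0 3-mer histogram
            c = cds[i : i + 3]
            oracle[c] = oracle.get(c, 0) + 1
        assert s.codon_counts == oracle


class TestRscu:
    def _summary(self, counts):
        return CodonUsageSummary(dict(counts), {}, sum(counts.values()), CODE)

    def test_uniform_two_fold(self):
        vals = rscu(self._summary({"TTT": 3, "TTC": 3}))
        assert vals["TTT"] == vals["TTC"] == pytest.approx(1.0)

    def test_extreme_two_fold(self):
        vals = rscu(self._summary({"TTT": 6}))
        assert vals["TTT"] == pytest.approx(2.0)
        assert vals["TTC"] == pytest.approx(0.0)

    def test_four_fold_hand_values(self):
        # Pro family CCN with counts 4,2,1,1 -> RSCU 2.0, 1.0, 0.5, 0.5
        vals = rscu(self._summary({"CCT": 4, "CCC": 2, "CCA": 1, "CCG": 1}))
        assert [vals[c] for c in ("CCT", "CCC", "CCA", "CCG")] == [2.0, 1.0, 0.5, 0.5]

    def test_absent_family_flagged_not_zero(self):
        vals = rscu(self._summary({"TTT": 1}))
        assert math.isnan(vals["CCT"])

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=4, max_size=4))
    def test_family_sum_equals_family_size(self, counts):
        fam = ("GTT", "GTC", "GTA", "GTG")  # Val, 4-fold
        vals = rscu(self._summary(dict(zip(fam, counts))))
        if sum(counts) > 0:
            assert sum(vals[c] for c in fam) == pytest.approx(4.0, abs=1e-9)


class TestClassifyRscu:
    def _summary(self, counts):
        return CodonUsageSummary(dict(counts), {}, sum(counts.values()), CODE)

    def test_thresholds_strict(self):
        # Leu 6-fold: craft counts giving RSCU exactly 0.6 and 1.6 on two codons
        counts = {"TTA": 16, "TTG": 6, "CTT": 8, "CTC": 10, "CTA": 10, "CTG": 10}
        vals = rscu(self._summary(counts))
        cls = classify_rscu(self._summary(counts))
        assert vals["TTA"] == pytest.approx(1.6)
        assert vals["TTG"] == pytest.approx(0.6)
        assert cls["TTA"] == "neutral" and cls["TTG"] == "neutral"

    def test_over_under_unused_absent(self):
        counts = {"TTA": 17, "TTG": 5, "CTT": 8, "CTC": 10, "CTA": 20}
        cls = classify_rscu(self._summary(counts))
        assert cls["TTA"] == "overrepresented"   # 17/10 = 1.7
        assert cls["TTG"] == "underrepresented"  # 0.5
        assert cls["CTG"] == "unused"            # count 0, family present
        assert cls["GGG"] == "absent"            # Gly family entirely absent

    def test_matches_brute_force_threshold_scan(self, rng):
        # Dirichlet-skewed pooled counts, alpha=0.1 as a stress fixture
        probs = rng.dirichlet([0.1] * 62)
        draws = rng.multinomial(5000, probs)
        counts = {c: int(n) for c, n in zip(CODE.sense_codons, draws)}
        summary = CodonUsageSummary(counts, {}, sum(counts.values()), CODE)
        vals, cls = rscu(summary), classify_rscu(summary)
        for aa, cods in CODE.families().items():
            total = sum(counts.get(c, 0) for c in cods)
            for c in cods:
                if total == 0:
                    expect = "absent"
                elif counts.get(c, 0) == 0:
                    expect = "unused"
                elif vals[c] > 1.6:
                    expect = "overrepresented"
                elif vals[c] < 0.6:
                    expect = "underrepresented"
                else:
                    expect = "neutral"
                assert cls[c] == expect


class TestGcPositions:
    def test_hand_count(self):
        s = count_codons(["ATGTTT"], CODE)
        gc1, gc2, gc3, gc12 = gc_positions(s)
        assert (gc1, gc2, gc3) == (0.0, 0.0, 0.5)
        assert gc12 == pytest.approx((gc1 + gc2) / 2)

    def test_uniform_usage_matches_enumeration(self):
        counts = {c: 1 for c in CODE.sense_codons}
        s = CodonUsageSummary(counts, {}, 62, CODE)
        _, _, gc3, _ = gc_positions(s)
        oracle = sum(c[2] in "GC" for c in CODE.sense_codons) / 62
        assert gc3 == pytest.approx(oracle)
        assert oracle == pytest.approx(31 / 62)  # TAG is the only G/C-ending stop

    def test_degenerate_single_codon(self):
        s = count_codons(["GCG" * 10], CODE)
        assert gc_positions(s)[:3] == (1.0, 1.0, 1.0)

    def test_empty_flagged(self):
        s = CodonUsageSummary({}, {}, 0, CODE)
        assert all(math.isnan(v) for v in gc_positions(s))


def _brute_force_enc(counts, code):
    """Independent ENC implementation: literal Wright class sum."""
    fams = code.families()
    by_size: dict = {}
    for aa, cods in fams.items():
        ns = [counts.get(c, 0) for c in cods]
        n = sum(ns)
        if n < 2:
            f = None
        else:
            f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
            if f <= 0:
                f = None
        by_size.setdefault(len(cods), []).append(f)
    total = 0.0
    fbar = {}
    for size, fs in by_size.items():
        ok = [f for f in fs if f is not None]
        fbar[size] = sum(ok) / len(ok) if ok else None
    for size in by_size:
        if fbar[size] is None:
            fbar[size] = fbar.get(4)
        total += len(by_size[size]) / fbar[size]
    return min(max(total, 20.0), len(code.sense_codons))


class TestEnc:
    def test_single_codon_per_amino_acid_is_exactly_20(self):
        cds = "".join(cods[0] * 3 for cods in CODE.families().values())
        assert enc(count_codons([cds], CODE)) == 20.0

    def test_uniform_usage_approaches_sense_codon_count(self, rng):
        draws = rng.choice(CODE.sense_codons, size=50_000)
        counts: dict = {}
        for c in draws:
            counts[c] = counts.get(c, 0) + 1
        s = CodonUsageSummary(counts, {}, 50_000, CODE)
        assert enc(s) == pytest.approx(62.0, abs=0.5)

    def test_matches_independent_implementation(self, rng):
        for _ in range(10):
            probs = rng.dirichlet([0.3] * 62)
            draws = rng.multinomial(800, probs)
            counts = {c: int(n) for c, n in zip(CODE.sense_codons, draws) if n}
            s = CodonUsageSummary(counts, {}, sum(counts.values()), CODE)
            assert enc(s) == pytest.approx(_brute_force_enc(counts, CODE), abs=1e-9)

    def test_fixed_table_one_family_per_class(self):
        # Phe 2-fold (3,1), Val 4-fold (4,2,1,1), Leu (2,2,1,1,0,0), Ser 8x1
        counts = {
            "TTT": 3, "TTC": 1,
            "GTT": 4, "GTC": 2, "GTA": 1, "GTG": 1,
            "TTA": 2, "TTG": 2, "CTT": 1, "CTC": 1,
            "TCT": 1, "TCC": 1, "TCA": 1, "TCG": 1,
            "AGT": 1, "AGC": 1, "AGA": 1, "AGG": 1,
        }
        s = CodonUsageSummary(counts, {}, sum(counts.values()), CODE)
        assert enc(s) == pytest.approx(_brute_force_enc(counts, CODE), abs=1e-9)

    def test_scaling_counts_is_monotone_and_convergent(self):
        base = {"TTT": 3, "TTC": 1, "GTT": 2, "GTC": 1, "GTA": 1,
                "TTA": 2, "TTG": 1, "TCT": 2, "AGA": 1}
        values = []
        for k in (1, 2, 4, 8, 64, 512, 4096):
            counts = {c: k * n for c, n in base.items()}
            s = CodonUsageSummary(counts, {}, sum(counts.values()), CODE)
            values.append(enc(s))
        # finite-sample correction relaxes as counts scale: ENC non-increasing
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-2] == pytest.approx(values[-1], abs=0.05)

    def test_bounds_after_clipping(self, rng):
        for _ in range(20):
            probs = rng.dirichlet([0.05] * 62)
            draws = rng.multinomial(200, probs)
            counts = {c: int(n) for c, n in zip(CODE.sense_codons, draws) if n}
            s = CodonUsageSummary(counts, {}, sum(counts.values()), CODE)
            v = enc(s)
            assert 20.0 <= v <= 62.0

    def test_no_counts_is_undefined(self):
        s = CodonUsageSummary({}, {}, 0, CODE)
        assert math.isnan(enc(s))


class TestEncExpected:
    def test_closed_form_at_half(self):
        assert enc_expected(0.5) == pytest.approx(2.5 + 29 / 0.5)  # 60.5

    def test_limits(self):
        assert enc_expected(0.0) == pytest.approx(31.0)
        assert enc_expected(1.0) == pytest.approx(32.0)

    def test_maximum_near_half_by_grid_search(self):
        # the linear +s term nudges the peak ~0.002 above 1/2
        grid = np.linspace(0.001, 0.999, 999)
        vals = [enc_expected(s) for s in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.5, abs=0.005)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)
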