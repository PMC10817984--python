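"""Community statistics: marker profiles, proteome proxies, diversity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.diversity import alpha as skbio_alpha

from plastideg import DataWarning, EmptyMarkerError, InvalidInputError
from plastideg.community import (
    chao1,
    community_aa_matrix,
    community_z_c,
    coverage_rarefy,
    diversity_rate_association,
    f_ivywrel,
    filter_rpsc_for_tree,
    goods_coverage,
    protein_elemental_composition,
    rpsc_relative_frequency,
    shannon,
    t_opt,
    z_c,
)

from conftest import orf_table

# Free amino-acid molecular formulas (C, H, N, O, S) — the independent
# bookkeeping used as an oracle for peptide compositions below.
FREE_AA = {
    "G": (2, 5, 1, 2, 0), "A": (3, 7, 1, 2, 0), "S": (3, 7, 1, 3, 0),
    "P": (5, 9, 1, 2, 0), "V": (5, 11, 1, 2, 0), "T": (4, 9, 1, 3, 0),
    "C": (3, 7, 1, 2, 1), "L": (6, 13, 1, 2, 0), "I": (6, 13, 1, 2, 0),
    "N": (4, 8, 2, 3, 0), "D": (4, 7, 1, 4, 0), "Q": (5, 10, 2, 3, 0),
    "K": (6, 14, 2, 2, 0), "E": (5, 9, 1, 4, 0), "M": (5, 11, 1, 2, 1),
    "H": (6, 9, 3, 2, 0), "F": (9, 11, 1, 2, 0), "R": (6, 14, 4, 2, 0),
    "Y": (9, 11, 1, 3, 0), "W": (11, 12, 2, 2, 0),
}


def peptide_atoms(seq):
    """Oracle: sum free amino acids, remove one water per peptide bond."""
    totals = [0] * 5
    for ch in seq:
        for i in range(5):
            totals[i] += FREE_AA[ch][i]
    n_bonds = len(seq) - 1
    totals[1] -= 2 * n_bonds
    totals[3] -= n_bonds
    return tuple(totals)


class TestMarkerProfile:
    def test_single_marker(self):
        table = orf_table([{"coverage": 5.0, "seq": "M" * 100, "genus": "A", "is_rpsC": True}])
        profile = rpsc_relative_frequency(table)
        assert profile.frequencies.to_dict() == {"A": 1.0}

    def test_coverage_times_length_weighting(self):
        table = orf_table(
            [
                {"coverage": 10.0, "length": 200, "genus": "A", "is_rpsC": True},
                {"coverage": 30.0, "length": 100, "genus": "B", "is_rpsC": True},
            ]
        )
        freqs = rpsc_relative_frequency(table).frequencies
        assert freqs["A"] == pytest.approx(0.4)
        assert freqs["B"] == pytest.approx(0.6)

    def test_duplicate_markers_add(self):
        table = orf_table(
            [
                {"coverage": 10.0, "length": 100, "genus": "A", "is_rpsC": True},
                {"coverage": 10.0, "length": 100, "genus": "A", "is_rpsC": True},
                {"coverage": 20.0, "length": 100, "genus": "B", "is_rpsC": True},
            ]
        )
        freqs = rpsc_relative_frequency(table).frequencies
        assert freqs["A"] == pytest.approx(0.5)

    def test_no_markers_is_an_error(self):
        table = orf_table([{"coverage": 5.0, "length": 100}])
        with pytest.raises(EmptyMarkerError):
            rpsc_relative_frequency(table)

    def test_class_coarsening_preserves_total(self, rng):
        rows = [
            {
                "coverage": float(rng.uniform(1, 50)),
                "length": int(rng.integers(100, 400)),
                "genus": f"g{i % 7}",
                "class": f"c{i % 3}",
                "is_rpsC": True,
            }
            for i in range(30)
        ]
        table = orf_table(rows)
        for level in ("genus", "class"):
            total = rpsc_relative_frequency(table, level).frequencies.sum()
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_frequencies_sum_to_one_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 12))
            rows = [
                {
                    "coverage": float(rng.uniform(0.1, 100)),
                    "length": int(rng.integers(50, 500)),
                    "genus": f"g{rng.integers(0, 5)}",
                    "is_rpsC": True,
                }
                for _ in range(n)
            ]
            freqs = rpsc_relative_frequency(orf_table(rows)).frequencies
            assert freqs.sum() == pytest.approx(1.0, abs=1e-9)
            assert (freqs >= 0).all()


class TestTreeFilter:
    def test_boundaries_are_strict(self):
        table = orf_table(
            [
                {"coverage": 10.0, "length": 200, "is_rpsC": True},  # boundary cov
                {"coverage": 11.0, "length": 151, "is_rpsC": True},  # passes
                {"coverage": 50.0, "length": 150, "is_rpsC": True},  # boundary len
                {"coverage": 9.0, "length": 400, "is_rpsC": True},
                {"coverage": 12.0, "length": 300, "is_rpsC": True},  # passes
            ]
        )
        kept = filter_rpsc_for_tree(table)
        assert list(kept["orf_id"]) == ["orf1", "orf4"]

    def test_empty_result_allowed(self):
        table = orf_table([{"coverage": 1.0, "length": 10, "is_rpsC": True}])
        assert filter_rpsc_for_tree(table).empty


class TestAminoAcidMatrix:
    def test_single_orf(self):
        matrix = community_aa_matrix(orf_table([{"coverage": 5.0, "seq": "GG"}]))
        assert matrix.weighted_counts["G"] == 10.0
        assert matrix.total == 10.0

    def test_weighted_sum(self):
        table = orf_table([
            {"coverage": 1.0, "seq": "AG"},
            {"coverage": 3.0, "seq": "A"},
        ])
        matrix = community_aa_matrix(table)
        assert matrix.weighted_counts["A"] == 4.0
        assert matrix.weighted_counts["G"] == 1.0
        assert matrix.total == 5.0

    def test_nonstandard_excluded_but_tracked(self):
        matrix = community_aa_matrix(orf_table([{"coverage": 2.0, "seq": "AXG"}]))
        assert matrix.total == 4.0
        assert matrix.excluded_nonstandard == 2.0

    def test_zero_coverage_degenerate(self):
        with pytest.raises(InvalidInputError):
            community_aa_matrix(orf_table([{"coverage": 0.0, "seq": "AG"}]))


class TestThermophilyProxy:
    def test_pure_ivywrel_protein(self):
        matrix = community_aa_matrix(orf_table([{"coverage": 1.0, "seq": "IVYWREL"}]))
        assert f_ivywrel(matrix) == 1.0

    def test_no_ivywrel_protein(self):
        matrix = community_aa_matrix(orf_table([{"coverage": 1.0, "seq": "GGGG"}]))
        assert f_ivywrel(matrix) == 0.0

    def test_one_of_three(self):
        matrix = community_aa_matrix(orf_table([{"coverage": 1.0, "seq": "LAG"}]))
        assert f_ivywrel(matrix) == pytest.approx(1 / 3)

    def test_invariant_to_uniform_coverage_rescaling(self, rng):
        rows = [
            {"coverage": float(c), "seq": "".join(rng.choice(list("IVYWRELAGKDS"), 50))}
            for c in rng.uniform(1, 10, size=5)
        ]
        table = orf_table([dict(r) for r in rows])
        scaled = table.copy()
        scaled["coverage"] *= 7.5
        assert f_ivywrel(community_aa_matrix(table)) == pytest.approx(
            f_ivywrel(community_aa_matrix(scaled)), rel=1e-12
        )

    def test_t_opt_line(self):
        assert t_opt(335.0 / 937.0) == pytest.approx(0.0, abs=1e-9)
        assert t_opt(0.40) == pytest.approx(39.8)
        with pytest.warns(DataWarning):
            assert t_opt(0.0) == -335.0
        with pytest.raises(InvalidInputError):
            t_opt(1.2)

    @given(f1=st.floats(0, 1), f2=st.floats(0, 1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_t_opt_strictly_increasing(self, f1, f2):
        if abs(f1 - f2) < 1e-9:  # below float resolution of the 937x map
            return
        lo, hi = sorted((f1, f2))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert t_opt(lo) < t_opt(hi)


class TestElementalComposition:
    @pytest.mark.parametrize("residue", list(FREE_AA))
    def test_residue_table_matches_free_amino_acids(self, residue):
        assert protein_elemental_composition({residue: 1}) == FREE_AA[residue]

    def test_diglycine(self):
        assert protein_elemental_composition({"G": 2}) == (4, 8, 2, 3, 0)

    @pytest.mark.parametrize("seq", ["GAVLK", "WWRD", "MCSTPHQNEFYI"])
    def test_peptides_match_atom_enumeration(self, seq):
        counts = {ch: seq.count(ch) for ch in set(seq)}
        assert protein_elemental_composition(counts) == peptide_atoms(seq)

    def test_unknown_residue_named(self):
        with pytest.raises(InvalidInputError, match="'X'"):
            protein_elemental_composition({"X": 1})


class TestZc:
    def test_glycine(self):
        assert z_c((2, 5, 1, 2, 0)) == 1.0

    def test_alanine(self):
        assert z_c((3, 7, 1, 2, 0)) == 0.0

    def test_methane(self):
        assert z_c((1, 4, 0, 0, 0)) == -4.0

    def test_carbonless_rejected(self):
        with pytest.raises(InvalidInputError):
            z_c((0, 2, 0, 1, 0))

    def test_identical_proteins_give_protein_z_c(self):
        table = orf_table([
            {"coverage": 2.0, "seq": "GAVK"},
            {"coverage": 5.0, "seq": "GAVK"},
        ])
        expected = z_c(peptide_atoms("GAVK"))
        assert community_z_c(table) == pytest.approx(expected, rel=1e-12)

    def test_equal_coverage_equal_carbon_is_arithmetic_mean(self):
        a1, a2 = peptide_atoms("GGG"), peptide_atoms("AA")  # both 6 C
        assert a1[0] == a2[0] == 6
        table = orf_table([
            {"coverage": 3.0, "seq": "GGG"},
            {"coverage": 3.0, "seq": "AA"},
        ])
        expected = (z_c(a1) + z_c(a2)) / 2.0
        assert community_z_c(table) == pytest.approx(expected, rel=1e-12)

    def test_three_taxon_table_matches_atom_oracle(self, rng):
        seqs = ["GAVLKWRD", "MCSTP", "HQNEFYIVA", "RRKKDDEE"]
        covs = [1.5, 3.0, 0.5, 7.25]
        table = orf_table([{"coverage": c, "seq": s} for c, s in zip(covs, seqs)])
        num = sum(
            c * (2 * (a[3] + a[4]) + 3 * a[2] - a[1])
            for c, a in zip(covs, (peptide_atoms(s) for s in seqs))
        )
        den = sum(c * peptide_atoms(s)[0] for c, s in zip(covs, seqs))
        assert community_z_c(table) == pytest.approx(num / den, rel=1e-12)


class TestAlphaDiversity:
    def test_uniform_is_log_richness(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(math.log(4), rel=1e-12)

    def test_single_taxon_zero(self):
        assert shannon([10]) == 0.0

    def test_direct_evaluation(self):
        assert shannon([1, 2, 3]) == pytest.approx(1.0114, abs=1e-3)

    def test_base_conversion(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            shannon([0, 0])

    def test_matches_reference_implementation(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=30)
            if counts.sum() == 0:
                continue
            assert shannon(counts) == pytest.approx(
                float(skbio_alpha.shannon(counts)), rel=1e-9
            )

    def test_chao1_examples(self):
        assert chao1([3, 4, 5]) == 3.0  # no singletons
        assert chao1([1, 1, 2, 5, 5]) == 5.5
        assert chao1([1, 1, 1, 1]) == 10.0

    def test_chao1_matches_reference_implementation(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 6, size=40)
            if counts.sum() == 0:
                continue
            assert chao1(counts) == pytest.approx(
                float(skbio_alpha.chao1(counts, bias_corrected=True)), rel=1e-9
            )

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=50))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_shannon_bound_and_chao1_floor(self, counts):
        arr = np.asarray(counts)
        if arr.sum() == 0:
            return
        s_obs = int((arr > 0).sum())
        assert shannon(arr) <= math.log(s_obs) + 1e-12
        assert chao1(arr) >= s_obs


class TestCoverageRarefaction:
    def test_goods_formula(self):
        counts = np.array([95] + [1] * 5)  # n = 100, F1 = 5
        assert goods_coverage(counts) == pytest.approx(0.95)

    def test_no_singletons_full_coverage(self):
        counts = np.array([10, 20, 30])
        assert goods_coverage(counts) == 1.0
        # standardising at coverage 1.0 keeps a singleton-free subsample
        result = coverage_rarefy(counts, 1.0, seed=1)
        assert result.coverage == 1.0
        assert (result.counts[result.counts > 0] >= 2).all()
        # standardising at 0.99 subsamples down to where the target is met
        result99 = coverage_rarefy(counts, 0.99, seed=1)
        assert result99.depth < counts.sum()
        assert result99.counts.sum() == result99.depth

    def test_deterministic_given_seed(self, rng):
        counts = rng.multinomial(3000, np.full(60, 1 / 60))
        r1 = coverage_rarefy(counts, 0.99, seed=42)
        r2 = coverage_rarefy(counts, 0.99, seed=42)
        assert np.array_equal(r1.counts, r2.counts)
        r3 = coverage_rarefy(counts, 0.99, seed=43)
        assert r1.depth == r3.depth  # depth is seed-independent

    def test_subsample_hits_target_coverage(self, rng):
        counts = rng.multinomial(5000, np.random.default_rng(3).dirichlet(np.ones(100)))
        result = coverage_rarefy(counts, 0.99, seed=7)
        assert result.depth <= counts.sum()
        assert result.counts.sum() == result.depth
        assert result.coverage >= 0.97  # realised coverage near target

    def test_low_coverage_sample_dropped(self):
        counts = np.ones(50, dtype=int)  # all singletons: coverage 0
        with pytest.warns(DataWarning):
            result = coverage_rarefy(counts, 0.99, seed=0)
        assert result.counts is None

    def test_invalid_target(self):
        with pytest.raises(InvalidInputError):
            coverage_rarefy([5, 6, 7], target_coverage=1.5)


class TestAssociation:
    def test_perfect_monotone(self):
        down = diversity_rate_association([5, 4, 3, 2], [1, 2, 3, 4])
        up = diversity_rate_association([1, 2, 3, 4], [1, 2, 3, 4])
        assert down.rho == -1.0
        assert up.rho == 1.0

    def test_constant_vector_sentinel(self):
        res = diversity_rate_association([1.0, 1.0, 1.0], [1, 2, 3])
        assert math.isnan(res.rho)

    def test_noisy_gradient_detected(self, rng):
        rates = rng.uniform(0, 100, size=50)
        diversity = 5.0 - 0.03 * rates + rng.normal(0, 0.4, size=50)
        res = diversity_rate_association(diversity, rates)
        assert res.rho < -0.5
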