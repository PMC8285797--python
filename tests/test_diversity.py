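"""Allelic diversity statistics: counts, private alleles, heterozygosity,
rarefied allelic richness (with exhaustive-enumeration oracles)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blockdiv import diversity
from blockdiv.blocks import allele_count_array

from conftest import single_block_dataset


class TestAlleleCounts:
    def test_two_animal_breed_frequencies(self):
        """Haplotypes {a,a,b,c} give frequencies {0.5, 0.25, 0.25}."""
        blk = single_block_dataset(
            {"X": [("0000", "0000"), ("0001", "0011")], "Y": [("0000", "0000")]}
        )
        breeds, counts = diversity.allele_counts(blk)
        freq = diversity.allele_frequencies(counts)
        x = freq[breeds.index("X"), 0]
        assert sorted(x[x > 0].tolist(), reverse=True) == [0.5, 0.25, 0.25]

    def test_frequencies_sum_to_one(self, small_blocks):
        breeds, counts = diversity.allele_counts(small_blocks)
        freq = diversity.allele_frequencies(counts)
        sums = freq.sum(axis=2)
        assert np.allclose(sums, 1.0)

    def test_counts_match_direct_tally(self, small_panel, small_blocks):
        ds, _ = small_panel
        breeds, counts = diversity.allele_counts(small_blocks)
        rng = np.random.default_rng(1)
        br = np.asarray(small_blocks.breeds)
        for b in rng.choice(small_blocks.n_blocks, size=5, replace=False):
            for k, breed in enumerate(breeds):
                idx = np.flatnonzero(br == breed)
                rows = np.sort(np.concatenate([2 * idx, 2 * idx + 1]))
                tally: dict[int, int] = {}
                for r in rows:
                    c = int(small_blocks.codes[r, int(b)])
                    tally[c] = tally.get(c, 0) + 1
                for code, n in tally.items():
                    assert counts[k, int(b), code] == n


class TestPrivateAlleles:
    def test_semiprivate_credited_to_both_breeds(self):
        blk = single_block_dataset(
            {
                "X": [("0000", "0001")],
                "Y": [("0001", "0011")],
                "Z": [("0011", "0011")],
            }
        )
        # 0000 private to X; 0001 in X+Y (semiprivate both); 0011 in Y+Z
        breeds, counts = diversity.allele_counts(blk)
        table = diversity.private_semiprivate(breeds, counts)
        assert table.loc["X", "npA"] == 1
        assert table.loc["X", "nrA"] == 1
        assert table.loc["Y", "npA"] == 0
        assert table.loc["Y", "nrA"] == 2
        assert table.loc["Z", "npA"] == 0
        assert table.loc["Z", "nrA"] == 1

    def test_identical_breeds_have_no_private_alleles(self):
        blk = single_block_dataset(
            {"X": [("0000", "0001")], "Y": [("0000", "0001")]}
        )
        breeds, counts = diversity.allele_counts(blk)
        table = diversity.private_semiprivate(breeds, counts)
        assert (table["npA"] == 0).all()

    def test_removing_shared_breed_makes_allele_private(self):
        """Dropping a third breed that shared an allele with X upgrades the
        allele from semiprivate to private in the reduced design."""
        blk = single_block_dataset(
            {
                "X": [("0000", "0001")],
                "Y": [("0001", "0011")],
                "Z": [("0011", "1111")],
            }
        )
        full_breeds, full_counts = diversity.allele_counts(blk)
        full = diversity.private_semiprivate(full_breeds, full_counts)
        assert full.loc["X", "npA"] == 1  # 0000 only
        reduced = blk.subset_samples(
            [s for s, b in zip(blk.sample_ids, blk.breeds) if b != "Y"]
        )
        red_breeds, red_counts = diversity.allele_counts(reduced)
        red = diversity.private_semiprivate(red_breeds, red_counts)
        assert red.loc["X", "npA"] == 2  # 0001 became private too

    def test_mpAf_is_within_owner_frequency(self):
        blk = single_block_dataset(
            {"X": [("0000", "0000"), ("0000", "0001")], "Y": [("0011", "0011")]}
        )
        breeds, counts = diversity.allele_counts(blk)
        table = diversity.private_semiprivate(breeds, counts)
        # X private alleles: 0000 (3/4) and 0001 (1/4) -> mean 0.5
        assert table.loc["X", "mpAf"] == pytest.approx(0.5)

    def test_classification_partitions_alleles(self, small_blocks):
        """Every observed allele is private, semiprivate or common in
        exactly one category per owning breed."""
        breeds, counts = diversity.allele_counts(small_blocks)
        present = counts > 0
        n_with = present.sum(axis=0)
        table = diversity.private_semiprivate(breeds, counts)
        for k, b in enumerate(breeds):
            own = present[k]
            n_private = int((own & (n_with == 1)).sum())
            n_semi = int((own & (n_with == 2)).sum())
            n_common = int((own & (n_with >= 3)).sum())
            assert n_private == table.loc[b, "npA"]
            assert n_semi == table.loc[b, "nrA"]
            assert n_private + n_semi + n_common == own.sum()


class TestHeterozygosity:
    def test_fixed_block_is_zero_zero(self):
        blk = single_block_dataset({"X": [("0000", "0000"), ("0000", "0000")]})
        het = diversity.heterozygosity(blk)
        assert het.loc["X", "Ho"] == 0.0
        assert het.loc["X", "He"] == 0.0
        assert np.isnan(het.loc["X", "Hdef"])

    def test_even_two_allele_block_he_half(self):
        blk = single_block_dataset(
            {"X": [("0000", "0001"), ("0001", "0000")]}
        )
        het = diversity.heterozygosity(blk)
        assert het.loc["X", "He"] == pytest.approx(0.5)
        assert het.loc["X", "Ho"] == 1.0

    def test_hdef_printed_rounding(self):
        assert diversity.heterozygosity_deficiency(0.85, 0.83) == pytest.approx(
            -0.024, abs=5e-4
        )
        assert round(diversity.heterozygosity_deficiency(0.85, 0.83), 2) == -0.02

    def test_he_invariant_under_code_relabeling(self, small_blocks):
        het = diversity.heterozygosity(small_blocks)
        relabeled = small_blocks.subset_samples(list(small_blocks.sample_ids))
        relabeled.allele_strings = list(relabeled.allele_strings)  # unshare
        # permute codes consistently within one block
        b = 0
        k = len(relabeled.allele_strings[b])
        if k > 1:
            perm = np.roll(np.arange(k), 1)
            relabeled.codes[:, b] = perm[relabeled.codes[:, b]]
            relabeled.allele_strings[b] = [
                relabeled.allele_strings[b][int(np.flatnonzero(perm == i)[0])]
                for i in range(k)
            ]
        het2 = diversity.heterozygosity(relabeled)
        assert np.allclose(het["He"], het2["He"])
        assert np.allclose(het["Ho"], het2["Ho"])


def exhaustive_richness(copies: list[int], g: int) -> float:
    """Mean number of distinct alleles over all C(N, g) subsamples."""
    pool = [a for a, n in enumerate(copies) for _ in range(n)]
    vals = [len(set(sub)) for sub in itertools.combinations(pool, g)]
    return sum(vals) / len(vals)


class TestAllelicRichness:
    def test_fixed_allele_contributes_one(self):
        assert diversity.rarefied_richness(np.array([6]), 4) == pytest.approx(1.0)

    def test_two_by_two_example(self):
        """Copies {A,A,B,B} at g=2: all 6 subsamples average 10/6 distinct."""
        ar = diversity.rarefied_richness(np.array([2, 2]), 2)
        assert ar == pytest.approx(5.0 / 3.0)
        assert ar == pytest.approx(exhaustive_richness([2, 2], 2))

    def test_g_equals_n_returns_observed_count(self):
        assert diversity.rarefied_richness(np.array([3, 2, 1]), 6) == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "copies,g",
        [
            ([4, 3, 2], 3),
            ([1, 1, 1, 1], 2),
            ([5, 1], 4),
            ([7, 3, 2], 6),
            ([2, 2, 2, 2, 2], 5),
            ([10, 1, 1], 8),
        ],
    )
    def test_matches_exhaustive_enumeration(self, copies, g):
        ar = diversity.rarefied_richness(np.array(copies), g)
        assert ar == pytest.approx(exhaustive_richness(copies, g), abs=1e-10)

    @given(
        st.lists(st.integers(1, 5), min_size=1, max_size=4),
        st.data(),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_subsample_size(self, copies, data):
        n = sum(copies)
        g = data.draw(st.integers(1, n - 1)) if n > 1 else 1
        a1 = diversity.rarefied_richness(np.array(copies), g)
        a2 = diversity.rarefied_richness(np.array(copies), min(g + 1, n))
        assert a2 >= a1 - 1e-12

    def test_rarefaction_larger_than_breed_is_error(self):
        blk = single_block_dataset(
            {"X": [("0000", "0001")], "Y": [("0011", "0011"), ("0011", "0000")]}
        )
        with pytest.raises(ValueError, match="X"):
            diversity.allelic_richness(blk, rarefy_to=4)


class TestDiversityTable:
    def test_table_schema_and_consistency(self, small_blocks):
        table = diversity.diversity_table(small_blocks)
        assert list(table.columns) == [
            "N", "nA", "mA", "npA", "nrA", "mpAf", "Ho", "He", "Hdef", "mAR",
        ]
        assert (table["npA"] <= table["nA"]).all()
        assert table["Ho"].between(0, 1).all()
        assert table["He"].between(0, 1).all()
        assert np.allclose(table["mA"], table["nA"] / small_blocks.n_blocks)
        # equal breed sizes: default rarefaction keeps all copies
        assert np.allclose(table["mAR"], table["mA"])

    def test_rarefied_mAR_below_mA(self, small_blocks):
        table = diversity.diversity_table(small_blocks, rarefy_to=10)
        assert (table["mAR"] < table["mA"] + 1e-12).all()
        assert (table["mAR"] <= table["mA"]).all()
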