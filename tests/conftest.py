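"""Shared fixtures: small simulated panels and hand-built block datasets."""

from __future__ import annotations

import numpy as np
import pytest

from blockdiv import blocks as blocks_mod
from blockdiv import simdata
from blockdiv.core import GenotypeDataset, make_snp_map


def small_config(seed: int = 11, **overrides) -> simdata.SimulationConfig:
    """Desk-scale study conditions: 3 breeds x 20 animals, 2,000 SNPs."""
    defaults = dict(
        n_breeds=3, n_per_breed=20, fst=0.1, n_snps=2000, n_chromosomes=5, seed=seed
    )
    defaults.update(overrides)
    return simdata.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_panel():
    """3 breeds x 20 animals, 2,000 SNPs, no injections (seed 11)."""
    ds, truth = simdata.simulate(small_config())
    return ds, truth


@pytest.fixture(scope="session")
def small_blocks(small_panel):
    ds, _ = small_panel
    bm = blocks_mod.build_block_map(ds.snps)
    return blocks_mod.encode_block_alleles(ds, bm)


def dataset_from_haplotypes(
    haps: list[str], breeds: list[str], spacing: int = 10_000
) -> GenotypeDataset:
    """Build a single-chromosome panel from explicit haplotype strings.

    ``haps`` holds two strings per sample (rows 2i, 2i+1), each a run of
    '0'/'1' characters, one per SNP; SNPs are laid out ``spacing`` bp
    apart so any four consecutive SNPs satisfy the block constraints.
    """
    n_snps = len(haps[0])
    hap = np.array([[int(c) for c in h] for h in haps], dtype=np.int8)
    snps = make_snp_map(
        [f"s{i + 1}" for i in range(n_snps)],
        ["1"] * n_snps,
        (np.arange(n_snps) * spacing + 1).tolist(),
    )
    ids = [f"{breeds[i]}_{i + 1}" for i in range(len(breeds))]
    return GenotypeDataset(ids, np.array(breeds, dtype=object), snps, hap, phased=True)


def single_block_dataset(
    breed_haplotypes: dict[str, list[tuple[str, str]]]
) -> blocks_mod.BlockAlleleDataset:
    """One 4-SNP block; each breed maps to a list of (gamete1, gamete2)
    4-character haplotype strings."""
    haps, breeds = [], []
    for breed, pairs in breed_haplotypes.items():
        for h1, h2 in pairs:
            haps.extend([h1, h2])
            breeds.append(breed)
    ds = dataset_from_haplotypes(haps, breeds)
    bm = blocks_mod.build_block_map(ds.snps)
    assert len(bm) == 1
    return blocks_mod.encode_block_alleles(ds, bm)
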