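"""Per-breed haplotype-block diversity statistics.

For every breed: total observed block alleles (nA), mean alleles per
block (mA), private and semiprivate allele counts (npA, nrA), mean
within-breed frequency of private alleles (mpAf), observed and expected
heterozygosity over blocks (Ho, He), heterozygosity deficiency
Hdef = (He - Ho) / He, and rarefied mean allelic richness (mAR)
standardised to a common number of gene copies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .blocks import MISSING_CODE, BlockAlleleDataset, allele_count_array


def allele_counts(blocks: BlockAlleleDataset) -> tuple[list[str], np.ndarray]:
    """Per-breed, per-block allele copy counts (n_breeds, n_blocks, 16)."""
    breeds, counts = allele_count_array(blocks)
    if any(counts[k].sum() == 0 for k in range(len(breeds))):
        raise ValueError("empty breed in block dataset")
    return breeds, counts


def allele_frequencies(counts: np.ndarray) -> np.ndarray:
    """Normalise copy counts to within-breed frequencies per block."""
    totals = counts.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, counts / totals, 0.0)
    return freq


def private_semiprivate(
    breeds: list[str], counts: np.ndarray
) -> pd.DataFrame:
    """npA, nrA and mpAf per breed.

    Private: allele observed in exactly one breed (owner).  Semiprivate:
    observed in exactly two breeds, credited to both.  mpAf is the mean
    within-owner frequency of the owner's private alleles.
    """
    present = counts > 0  # (K, B, 16)
    n_breeds_with = present.sum(axis=0)  # (B, 16)
    freq = allele_frequencies(counts)
    rows = []
    single = n_breeds_with == 1
    double = n_breeds_with == 2
    if len(breeds) == 1:
        warnings.warn("single breed: all alleles are private, nrA reported as 0")
    for k, b in enumerate(breeds):
        own_private = present[k] & single
        own_semi = present[k] & double
        np_a = int(own_private.sum())
        nr_a = 0 if len(breeds) == 1 else int(own_semi.sum())
        mp_af = float(freq[k][own_private].mean()) if np_a else np.nan
        rows.append({"breed": b, "npA": np_a, "nrA": nr_a, "mpAf": mp_af})
    return pd.DataFrame(rows).set_index("breed")


def heterozygosity(blocks: BlockAlleleDataset) -> pd.DataFrame:
    """Ho, He and Hdef per breed (unweighted means over blocks).

    Per block within a breed, Ho is the fraction of animals whose two
    block alleles differ and He the gene diversity 1 - sum p_a^2.
    """
    breeds, counts = allele_counts(blocks)
    freq = allele_frequencies(counts)
    he_blocks = 1.0 - (freq**2).sum(axis=2)  # (K, B)
    codes = blocks.codes
    br = np.asarray(blocks.breeds)
    rows = []
    for k, b in enumerate(breeds):
        idx = np.flatnonzero(br == b)
        c1 = codes[2 * idx]
        c2 = codes[2 * idx + 1]
        valid = (c1 != MISSING_CODE) & (c2 != MISSING_CODE)
        with np.errstate(invalid="ignore"):
            ho_blocks = np.where(
                valid.sum(axis=0) > 0,
                ((c1 != c2) & valid).sum(axis=0) / np.maximum(valid.sum(axis=0), 1),
                np.nan,
            )
        ho = float(np.nanmean(ho_blocks))
        he = float(he_blocks[k].mean())
        hdef = (he - ho) / he if he > 0 else np.nan
        rows.append({"breed": b, "Ho": ho, "He": he, "Hdef": hdef})
    return pd.DataFrame(rows).set_index("breed")


def observed_het_array(blocks: BlockAlleleDataset) -> tuple[list[str], np.ndarray]:
    """Per-breed, per-block fraction of heterozygous animals (K, B)."""
    breeds = blocks.breed_names()
    codes = blocks.codes
    br = np.asarray(blocks.breeds)
    out = np.zeros((len(breeds), blocks.n_blocks))
    for k, b in enumerate(breeds):
        idx = np.flatnonzero(br == b)
        c1 = codes[2 * idx]
        c2 = codes[2 * idx + 1]
        valid = (c1 != MISSING_CODE) & (c2 != MISSING_CODE)
        denom = np.maximum(valid.sum(axis=0), 1)
        out[k] = ((c1 != c2) & valid).sum(axis=0) / denom
    return breeds, out


def heterozygosity_deficiency(ho: float, he: float) -> float:
    """Hdef = (He - Ho) / He; positive when heterozygotes are deficient."""
    if he <= 0:
        raise ValueError("Hdef undefined for He <= 0")
    return (he - ho) / he


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def rarefied_richness(counts_block: np.ndarray, g: int) -> float:
    """Expected number of distinct alleles in a random subsample of ``g``
    gene copies from one breed-block allele-count vector (hypergeometric
    rarefaction): AR = sum_a [1 - C(N - N_a, g) / C(N, g)].
    """
    n_a = counts_block[counts_block > 0].astype(float)
    n = float(n_a.sum())
    if g > n:
        raise ValueError(f"rarefaction size {g} exceeds available copies {int(n)}")
    rest = n - n_a
    term = np.zeros_like(n_a)
    ok = rest >= g
    term[ok] = np.exp(_log_comb(rest[ok], g) - _log_comb(np.array(n), g))
    return float((1.0 - term).sum())


def allelic_richness(
    blocks: BlockAlleleDataset, rarefy_to: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-block AR and per-breed mean AR, rarefied to ``rarefy_to`` gene
    copies (default: twice the smallest breed sample size)."""
    breeds, counts = allele_counts(blocks)
    copies = counts.sum(axis=2)  # (K, B)
    if rarefy_to is None:
        rarefy_to = int(
            2 * min(np.sum(np.asarray(blocks.breeds) == b) for b in breeds)
        )
    g = int(rarefy_to)
    for k, b in enumerate(breeds):
        if np.any(copies[k] > 0) and copies[k][copies[k] > 0].min() < g:
            raise ValueError(
                f"rarefaction size {g} exceeds gene copies of breed {b}"
            )
    ar = np.empty((len(breeds), counts.shape[1]))
    for k in range(len(breeds)):
        for b in range(counts.shape[1]):
            ar[k, b] = rarefied_richness(counts[k, b], g)
    per_block = pd.DataFrame(
        ar.T, columns=breeds, index=blocks.block_map["block_id"]
    )
    return per_block, per_block.mean(axis=0).rename("mAR")


def diversity_table(
    blocks: BlockAlleleDataset, rarefy_to: int | None = None
) -> pd.DataFrame:
    """The per-breed diversity summary (one row per breed)."""
    breeds, counts = allele_counts(blocks)
    present = counts > 0
    n_animals = pd.Series(
        {b: int(np.sum(np.asarray(blocks.breeds) == b)) for b in breeds}
    )
    n_a = present.sum(axis=(1, 2))
    m_a = n_a / blocks.n_blocks
    priv = private_semiprivate(breeds, counts)
    het = heterozygosity(blocks)
    _, mar = allelic_richness(blocks, rarefy_to)
    out = pd.DataFrame(
        {
            "N": n_animals,
            "nA": pd.Series(n_a, index=breeds),
            "mA": pd.Series(m_a, index=breeds),
        }
    )
    out = out.join(priv).join(het).join(mar)
    out.index.name = "breed"
    return out
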