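"""Non-overlapping 4-SNP haplotype blocks and their integer-coded alleles.

Each block groups four consecutive SNPs on one chromosome whose adjacent
gaps are all below ``max_gap`` and whose first-to-last span stays below
``max_span``.  Within a block, every distinct 4-symbol phased haplotype is
one *block allele* of a multi-allelic marker (at most 2**4 = 16 alleles),
the unit for all downstream allelic-diversity statistics.  Using short
haplotypes instead of single array SNPs reduces the ascertainment bias of
medium-density chips toward intermediate-frequency variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeDataset

#: sentinel allele code for a haplotype with a missing call in the block
MISSING_CODE = 255

BLOCK_SIZE_DEFAULT = 4
MAX_GAP_DEFAULT = 50_000
MAX_SPAN_DEFAULT = 150_000


def build_block_map(
    snp_map: pd.DataFrame,
    block_size: int = BLOCK_SIZE_DEFAULT,
    max_gap: int = MAX_GAP_DEFAULT,
    max_span: int = MAX_SPAN_DEFAULT,
) -> pd.DataFrame:
    """Greedy left-to-right block construction per chromosome.

    A block opens at the current SNP and extends while each adjacent gap is
    strictly below ``max_gap`` and the running span strictly below
    ``max_span``; on violation the block restarts at the violating SNP.
    Trailing runs shorter than ``block_size`` are discarded.

    Returns a data frame with columns
    ``block_id, chrom, start, end, span, snp_indices`` where ``snp_indices``
    is a tuple of integer positions into ``snp_map``.
    """
    rows = []
    bid = 0
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        current: list[int] = [0]
        for j in range(1, len(idx)):
            if not current:  # fresh block opens at the SNP after an emitted block
                current = [j]
                continue
            gap = pos[j] - pos[j - 1]
            span = pos[j] - pos[current[0]]
            if gap >= max_gap or span >= max_span:
                current = [j]
                continue
            current.append(j)
            if len(current) == block_size:
                start, end = pos[current[0]], pos[current[-1]]
                rows.append(
                    {
                        "block_id": f"blk{bid + 1}",
                        "chrom": str(chrom),
                        "start": int(start),
                        "end": int(end),
                        "span": int(end - start),
                        "snp_indices": tuple(int(idx[k]) for k in current),
                    }
                )
                bid += 1
                current = []
        # trailing partial block discarded
    df = pd.DataFrame(
        rows, columns=["block_id", "chrom", "start", "end", "span", "snp_indices"]
    )
    return df


@dataclass
class BlockAlleleDataset:
    """Integer-coded block alleles: two rows per sample, one column per block.

    ``codes[2i + h, b]`` is the allele carried by gamete ``h`` of sample
    ``i`` at block ``b``; codes are dense per block, assigned in
    first-observed row order.  ``allele_strings[b][code]`` recovers the
    original 4-symbol haplotype.
    """

    sample_ids: list[str]
    breeds: np.ndarray
    block_map: pd.DataFrame
    codes: np.ndarray  # (2n, n_blocks) uint8
    allele_strings: list[list[str]]

    @property
    def n_blocks(self) -> int:
        return len(self.block_map)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def breed_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.breeds:
            seen.setdefault(str(b), None)
        return list(seen)

    def subset_samples(self, keep) -> "BlockAlleleDataset":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep_set]
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = np.asarray(idx) * 2
        rows[1::2] = np.asarray(idx) * 2 + 1
        return BlockAlleleDataset(
            [self.sample_ids[i] for i in idx],
            self.breeds[idx].copy(),
            self.block_map,
            self.codes[rows].copy(),
            self.allele_strings,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: sample, haplotype in {1,2}, block_id, allele_string."""
        recs = []
        for i, sid in enumerate(self.sample_ids):
            for h in (0, 1):
                row = self.codes[2 * i + h]
                for b, code in enumerate(row):
                    s = (
                        ""
                        if code == MISSING_CODE
                        else self.allele_strings[b][code]
                    )
                    recs.append((sid, h + 1, self.block_map["block_id"].iat[b], s))
        return pd.DataFrame(recs, columns=["sample", "haplotype", "block_id", "allele_string"])


def encode_block_alleles(
    dataset: GenotypeDataset,
    block_map: pd.DataFrame,
    drop_missing: bool = False,
) -> BlockAlleleDataset:
    """Map each gamete's 4-SNP haplotype in every block to a dense allele code.

    Requires complete phased genotypes over the block SNPs; with
    ``drop_missing`` a gamete pair carrying a missing call in a block is
    coded as absent for that block instead of raising.
    """
    if not dataset.phased:
        raise ValueError("phased input required")
    n2 = 2 * dataset.n_samples
    n_blocks = len(block_map)
    codes = np.empty((n2, n_blocks), dtype=np.uint8)
    allele_strings: list[list[str]] = []
    hap = dataset.haplotypes
    if n_blocks == 0:
        return BlockAlleleDataset(
            list(dataset.sample_ids), dataset.breeds.copy(), block_map, codes, []
        )
    block_size = len(block_map["snp_indices"].iat[0])
    idx_mat = np.array([list(t) for t in block_map["snp_indices"]])  # (B, size)
    sub = hap[:, idx_mat]  # (2n, B, size)
    bad = (sub == MISSING).any(axis=2)  # (2n, B)
    if bad.any() and not drop_missing:
        b = int(np.flatnonzero(bad.any(axis=0))[0])
        raise ValueError(
            f"missing call inside block {block_map['block_id'].iat[b]}; "
            "impute upstream or pass drop_missing=True"
        )
    if bad.any():
        # both gametes of an affected sample are dropped for the block
        bad = np.repeat(bad.reshape(-1, 2, n_blocks).any(axis=1), 2, axis=0)
    weights = 2 ** np.arange(block_size - 1, -1, -1)
    packed = (sub.astype(np.int64) * weights).sum(axis=2)  # (2n, B)
    packed[bad] = -1
    for b in range(n_blocks):
        col = np.full(n2, MISSING_CODE, dtype=np.uint8)
        valid = packed[:, b] >= 0
        inv, uniq = pd.factorize(packed[valid, b])  # first-observed order
        col[valid] = inv.astype(np.uint8)
        codes[:, b] = col
        allele_strings.append([format(int(v), f"0{block_size}b") for v in uniq])
    return BlockAlleleDataset(
        list(dataset.sample_ids), dataset.breeds.copy(), block_map, codes, allele_strings
    )


def allele_count_array(
    blocks: BlockAlleleDataset, max_alleles: int = 16
) -> tuple[list[str], np.ndarray]:
    """Per-breed allele-copy counts: (breeds, array of shape (n_breeds, n_blocks, max_alleles))."""
    breeds = blocks.breed_names()
    counts = np.zeros((len(breeds), blocks.n_blocks, max_alleles), dtype=np.int32)
    breed_index = {b: k for k, b in enumerate(breeds)}
    row_breed = np.repeat([breed_index[str(b)] for b in blocks.breeds], 2)
    n_blocks = blocks.n_blocks
    block_col = np.tile(np.arange(n_blocks), (blocks.codes.shape[0], 1))
    valid = blocks.codes != MISSING_CODE
    flat_breed = np.repeat(row_breed, n_blocks).reshape(-1, n_blocks)
    lin = (
        flat_breed[valid] * (n_blocks * max_alleles)
        + block_col[valid] * max_alleles
        + blocks.codes[valid]
    )
    np.add.at(counts.reshape(-1), lin, 1)
    return breeds, counts


def write_block_map(block_map: pd.DataFrame, path) -> None:
    out = block_map.copy()
    out["snp_indices"] = out["snp_indices"].map(lambda t: ",".join(map(str, t)))
    out.to_csv(path, sep="\t", index=False)
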