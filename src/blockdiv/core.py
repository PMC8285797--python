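"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`GenotypeDataset`: phased diploid haplotypes
over a SNP map, with one breed label per sample.  Haplotypes are stored as
an ``int8`` matrix with two rows per sample (rows ``2*i`` and ``2*i + 1``
belong to sample ``i``); allele codes are 0 (reference), 1 (alternate) and
-1 (missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: columns every SNP map carries, in order
SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


def make_snp_map(
    snp_id: Sequence[str],
    chrom: Sequence[str],
    pos: Sequence[int],
    ref: Sequence[str] | None = None,
    alt: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble and validate a SNP map (1-based positions, sorted per chromosome)."""
    n = len(snp_id)
    df = pd.DataFrame(
        {
            "snp_id": list(snp_id),
            "chrom": [str(c) for c in chrom],
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": list(ref) if ref is not None else ["A"] * n,
            "alt": list(alt) if alt is not None else ["G"] * n,
        }
    )
    for _, grp in df.groupby("chrom", sort=False):
        p = grp["pos"].to_numpy()
        if np.any(np.diff(p) <= 0):
            raise ValueError("SNP positions must be strictly increasing within a chromosome")
    return df


@dataclass
class GenotypeDataset:
    """Phased diploid genotypes for labelled samples.

    Parameters
    ----------
    sample_ids
        One identifier per animal.
    breeds
        Breed label per animal, aligned with ``sample_ids``.
    snps
        SNP map data frame with columns ``snp_id, chrom, pos, ref, alt``.
    haplotypes
        ``(2 * n_samples, n_snps)`` int8 matrix; rows ``2i, 2i+1`` are the
        two gametes of sample ``i``.
    phased
        Whether haplotype phase is meaningful.  Block encoding requires it.
    """

    sample_ids: list[str]
    breeds: np.ndarray
    snps: pd.DataFrame
    haplotypes: np.ndarray
    phased: bool = True

    def __post_init__(self) -> None:
        self.breeds = np.asarray(self.breeds, dtype=object)
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype row count must be 2 x sample count")
        if self.haplotypes.shape[1] != len(self.snps):
            raise ValueError("haplotype column count must match SNP map length")
        if len(self.breeds) != len(self.sample_ids):
            raise ValueError("one breed label per sample required")
        if any(not str(b) for b in self.breeds):
            raise ValueError("breed labels must be non-empty")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def breed_names(self) -> list[str]:
        """Breed labels in first-appearance order."""
        seen: dict[str, None] = {}
        for b in self.breeds:
            seen.setdefault(str(b), None)
        return list(seen)

    def breed_sizes(self) -> pd.Series:
        return pd.Series(self.breeds).value_counts().sort_index()

    def samples_of(self, breed: str) -> list[str]:
        return [s for s, b in zip(self.sample_ids, self.breeds) if b == breed]

    def index_of(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError as exc:
            raise KeyError(f"unknown sample {sample_id!r}") from exc

    # -- derived matrices --------------------------------------------------

    def dosage(self) -> np.ndarray:
        """Per-sample alternate-allele dosage in {0,1,2}; missing if any gamete missing."""
        h = self.haplotypes
        a, b = h[0::2], h[1::2]
        out = (a + b).astype(np.float64)
        out[(a == MISSING) | (b == MISSING)] = np.nan
        return out

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing gametes."""
        h = self.haplotypes
        valid = h != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(valid, h, 0).sum(axis=0) / valid.sum(axis=0)

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of samples with both gametes called."""
        h = self.haplotypes
        ok = (h[0::2] != MISSING) & (h[1::2] != MISSING)
        return ok.mean(axis=0)

    # -- subsetting --------------------------------------------------------

    def subset_samples(self, keep: Iterable[str]) -> "GenotypeDataset":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep_set]
        missing = keep_set - set(self.sample_ids)
        if missing:
            raise KeyError(f"samples not in dataset: {sorted(missing)}")
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = np.asarray(idx) * 2
        rows[1::2] = np.asarray(idx) * 2 + 1
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            breeds=self.breeds[idx].copy(),
            snps=self.snps.reset_index(drop=True),
            haplotypes=self.haplotypes[rows].copy(),
        )

    def subset_snps(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            snps=self.snps.loc[mask].reset_index(drop=True),
            haplotypes=self.haplotypes[:, mask].copy(),
        )

    def copy(self) -> "GenotypeDataset":
        return replace(
            self,
            sample_ids=list(self.sample_ids),
            breeds=self.breeds.copy(),
            snps=self.snps.copy(),
            haplotypes=self.haplotypes.copy(),
        )


@dataclass
class GroundTruth:
    """Per-animal simulation labels: purebred, admixed or member of a relative pair."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ["sample_id", "breed", "label", "donor", "alpha", "partner", "expected_uar"]

    @classmethod
    def purebred(cls, sample_ids: Sequence[str], breeds: Sequence[str]) -> "GroundTruth":
        df = pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "breed": list(breeds),
                "label": "purebred",
                "donor": "",
                "alpha": 0.0,
                "partner": "",
                "expected_uar": 0.0,
            }
        )
        return cls(df)

    def set_admixed(self, sample_id: str, donor: str, alpha: float) -> None:
        m = self.table["sample_id"] == sample_id
        self.table.loc[m, ["label", "donor", "alpha"]] = ["admixed", donor, alpha]

    def set_relative(self, sample_id: str, partner: str, expected_uar: float) -> None:
        m = self.table["sample_id"] == sample_id
        self.table.loc[m, ["label", "partner", "expected_uar"]] = [
            "relative",
            partner,
            expected_uar,
        ]

    def labels_of(self, label: str) -> list[str]:
        return self.table.loc[self.table["label"] == label, "sample_id"].tolist()
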