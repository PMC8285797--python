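"""Reading, writing and quality control of phased genotype panels.

Input is a phased VCF (``GT`` with ``|`` separators, read through cyvcf2)
or a plain haplotype table, plus a sample-to-breed TSV.  QC mirrors
standard array practice for diversity panels: per-SNP call rate and
pooled minor-allele-frequency filters, restriction to autosomes, and a
minimum number of genotyped animals per breed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeDataset, make_snp_map


class QCError(ValueError):
    """Raised when a filter leaves nothing usable."""


# ---------------------------------------------------------------------------
# reading


def read_breed_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "breed"} <= set(df.columns):
        raise ValueError("breed map must have columns: sample_id, breed")
    return df


def read_genotypes(path: str | Path, breed_map: str | Path) -> GenotypeDataset:
    """Load a phased VCF (.vcf) or haplotype table (.tsv/.txt) with breed labels."""
    path = Path(path)
    bm = read_breed_map(breed_map)
    breed_of = dict(zip(bm["sample_id"], bm["breed"]))
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        ds = _read_vcf(path, breed_of)
    else:
        ds = _read_hap_table(path, breed_of)
    return ds


def _check_breeds(sample_ids: list[str], breed_of: dict[str, str]) -> np.ndarray:
    missing = [s for s in sample_ids if s not in breed_of]
    if missing:
        raise ValueError(f"samples missing from breed map: {missing}")
    return np.array([breed_of[s] for s in sample_ids], dtype=object)


def _read_vcf(path: Path, breed_of: dict[str, str]) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    breeds = _check_breeds(sample_ids, breed_of)
    n = len(sample_ids)
    rows: list[np.ndarray] = []
    ids, chroms, pos, refs, alts = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"SNP {var.ID or var.POS} is not biallelic")
        g = np.asarray(var.genotype.array())
        called = (g[:, 0] >= 0) & (g[:, 1] >= 0)
        if np.any(~g[called, 2].astype(bool)):
            raise ValueError(
                f"phased input required: unphased genotype at {var.CHROM}:{var.POS}"
            )
        col = np.empty(2 * n, dtype=np.int8)
        col[0::2] = np.where(g[:, 0] >= 0, g[:, 0], MISSING)
        col[1::2] = np.where(g[:, 1] >= 0, g[:, 1], MISSING)
        rows.append(col)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if not rows:
        raise ValueError("empty VCF")
    snps = make_snp_map(ids, chroms, pos, refs, alts)
    hap = np.stack(rows, axis=1)
    return GenotypeDataset(sample_ids, breeds, snps, hap, phased=True)


def _read_hap_table(path: Path, breed_of: dict[str, str]) -> GenotypeDataset:
    """Long-format haplotype table: sample, haplotype (1|2), then one column per SNP.

    A companion map file ``<path>.map`` (snp_id, chrom, pos) provides positions.
    """
    df = pd.read_csv(path, sep="\t")
    map_path = Path(str(path) + ".map")
    snp_cols = [c for c in df.columns if c not in ("sample", "haplotype")]
    if map_path.exists():
        m = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
        snps = make_snp_map(m["snp_id"], m["chrom"], m["pos"])
    else:
        snps = make_snp_map(snp_cols, ["1"] * len(snp_cols), np.arange(1, len(snp_cols) + 1))
    sample_ids = list(dict.fromkeys(df["sample"]))
    breeds = _check_breeds(sample_ids, breed_of)
    hap = np.full((2 * len(sample_ids), len(snp_cols)), MISSING, dtype=np.int8)
    for _, row in df.iterrows():
        i = sample_ids.index(row["sample"])
        hap[2 * i + int(row["haplotype"]) - 1] = row[snp_cols].to_numpy(dtype=np.int8)
    return GenotypeDataset(sample_ids, breeds, snps, hap, phased=True)


# ---------------------------------------------------------------------------
# writing


def write_vcf(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write a minimal phased VCF (uncompressed text)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(dataset.snps["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.sample_ids)
            + "\n"
        )
        h = dataset.haplotypes
        for j, rec in enumerate(dataset.snps.itertuples(index=False)):
            a = h[0::2, j]
            b = h[1::2, j]
            gts = "\t".join(
                f"{x if x >= 0 else '.'}|{y if y >= 0 else '.'}" for x, y in zip(a, b)
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.snp_id}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_breed_map(dataset: GenotypeDataset, path: str | Path) -> None:
    pd.DataFrame({"sample_id": dataset.sample_ids, "breed": dataset.breeds}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# quality control


def autosome_labels(snps: pd.DataFrame) -> set[str]:
    """Chromosome labels that look autosomal (purely numeric, optional 'chr')."""
    out = set()
    for c in snps["chrom"].unique():
        s = str(c)
        if s.lower().startswith("chr"):
            s = s[3:]
        if s.isdigit():
            out.add(str(c))
    return out


def apply_snp_qc(
    dataset: GenotypeDataset,
    call_rate_min: float = 0.95,
    maf_min: float = 0.025,
    autosomes: set[str] | None = None,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Drop SNPs failing call-rate, MAF or autosome filters.

    MAF is computed on the pooled sample after the call-rate filter.
    Returns the filtered dataset and a per-removal report
    (snp_id, filter, value).
    """
    if autosomes is None:
        autosomes = autosome_labels(dataset.snps)
    records: list[tuple[str, str, float]] = []
    chrom = dataset.snps["chrom"].astype(str).to_numpy()
    auto_ok = np.isin(chrom, sorted(autosomes))
    cr = dataset.call_rate()
    cr_ok = cr >= call_rate_min
    p = dataset.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    maf_ok = maf >= maf_min
    keep = auto_ok & cr_ok & maf_ok
    snp_ids = dataset.snps["snp_id"].to_numpy()
    for j in np.flatnonzero(~auto_ok):
        records.append((snp_ids[j], "autosome", 0.0))
    for j in np.flatnonzero(auto_ok & ~cr_ok):
        records.append((snp_ids[j], "call_rate", float(cr[j])))
    for j in np.flatnonzero(auto_ok & cr_ok & ~maf_ok):
        records.append((snp_ids[j], "maf", float(maf[j])))
    if not keep.any():
        raise QCError("all SNPs removed by QC")
    report = pd.DataFrame(records, columns=["snp_id", "filter", "value"])
    return dataset.subset_snps(keep), report


def apply_breed_inclusion(
    dataset: GenotypeDataset, min_n: int = 14
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Drop entire breeds with fewer than ``min_n`` genotyped animals."""
    sizes = dataset.breed_sizes()
    dropped = sizes[sizes < min_n]
    if len(dropped) == len(sizes):
        raise QCError("no breed satisfies the inclusion threshold")
    report = pd.DataFrame(
        {"breed": dropped.index, "n": dropped.to_numpy(), "action": "dropped"}
    )
    if len(dropped) == 0:
        return dataset, report
    keep = [
        s for s, b in zip(dataset.sample_ids, dataset.breeds) if b not in set(dropped.index)
    ]
    return dataset.subset_samples(keep), report


def require_complete_phased(dataset: GenotypeDataset) -> None:
    """Block encoding needs fully called, phased haplotypes."""
    if not dataset.phased:
        raise ValueError("phased input required")
    if np.any(dataset.haplotypes == MISSING):
        raise ValueError(
            "missing genotype calls present; impute upstream or enable per-block dropping"
        )
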