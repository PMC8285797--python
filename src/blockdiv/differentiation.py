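"""Pairwise differentiation over block alleles and a minimal PCA.

Estimators follow the Nei-Chesser sample-size corrections with the
harmonic mean n~ of the two breed sample sizes (in animals) and the
observed heterozygosity Ho (mean of the two breeds): per block

    Hs_hat = n~ / (n~ - 1) * (1 - (sum_a p1_a^2 + sum_a p2_a^2)/2 - Ho/(2 n~))
    Ht_hat = 1 - sum_a p_bar_a^2 + Hs_hat / (n~ s) - Ho / (2 n~ s),  s = 2 pops

with components averaged over blocks before forming

    G_ST  = (Ht - Hs) / Ht
    D_est = (Ht - Hs) / (1 - Hs) * s / (s - 1)        (Jost)

D_est is independent of within-population heterozygosity, which makes it
the preferred differentiation measure for highly polymorphic block
alleles; G_ST saturates when Hs is large.  Nei's D_A distance is
1 - (1/L) sum_blocks sum_a sqrt(x_a * y_a) on raw frequencies.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import BlockAlleleDataset
from .core import GenotypeDataset
from .diversity import allele_counts, allele_frequencies, observed_het_array

_METRICS = ("GST", "DEST", "NeiDA")


def _components_per_block(
    counts: np.ndarray, freq: np.ndarray, ho: np.ndarray, i: int, j: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block (Hs_hat, Ht_hat) arrays for one breed pair."""
    n_i = counts[i].sum(axis=1) / 2.0  # animals per block
    n_j = counts[j].sum(axis=1) / 2.0
    usable = (n_i > 1) & (n_j > 1)
    if not usable.any():
        raise ValueError("no usable blocks for this breed pair")
    p1 = freq[i][usable]
    p2 = freq[j][usable]
    ho_mean = (ho[i][usable] + ho[j][usable]) / 2.0
    n_tilde = 2.0 / (1.0 / n_i[usable] + 1.0 / n_j[usable])
    hs_raw = 1.0 - ((p1**2).sum(axis=1) + (p2**2).sum(axis=1)) / 2.0
    hs = n_tilde / (n_tilde - 1.0) * (hs_raw - ho_mean / (2.0 * n_tilde))
    pbar = (p1 + p2) / 2.0
    ht = (
        1.0
        - (pbar**2).sum(axis=1)
        + hs / (2.0 * n_tilde)
        - ho_mean / (4.0 * n_tilde)
    )
    return hs, ht


def _pair_components(
    counts: np.ndarray, freq: np.ndarray, ho: np.ndarray, i: int, j: int
) -> tuple[float, float]:
    """Block-averaged (Hs_hat, Ht_hat) for one breed pair."""
    hs, ht = _components_per_block(counts, freq, ho, i, j)
    return float(hs.mean()), float(ht.mean())


def _count_tables(blocks: BlockAlleleDataset):
    breeds, counts = allele_counts(blocks)
    freq = allele_frequencies(counts)
    _, ho = observed_het_array(blocks)
    return breeds, counts, freq, ho


def pairwise_dest(
    blocks: BlockAlleleDataset, breed_a: str, breed_b: str, per_block: bool = False
) -> float:
    """Jost's D between two breeds (components averaged over blocks; set
    ``per_block`` to average per-block D values instead)."""
    breeds, counts, freq, ho = _count_tables(blocks)
    i, j = breeds.index(breed_a), breeds.index(breed_b)
    if per_block:
        hs, ht = _components_per_block(counts, freq, ho, i, j)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(hs < 1.0, (ht - hs) / (1.0 - hs) * 2.0, 0.0)
        return float(d.mean())
    hs, ht = _pair_components(counts, freq, ho, i, j)
    if hs >= 1.0:
        return 0.0
    return (ht - hs) / (1.0 - hs) * 2.0


def pairwise_gst(blocks: BlockAlleleDataset, breed_a: str, breed_b: str) -> float:
    breeds, counts, freq, ho = _count_tables(blocks)
    i, j = breeds.index(breed_a), breeds.index(breed_b)
    hs, ht = _pair_components(counts, freq, ho, i, j)
    if ht == 0:
        return float("nan")
    return (ht - hs) / ht


def nei_da(blocks: BlockAlleleDataset, breed_a: str, breed_b: str) -> float:
    breeds, counts = allele_counts(blocks)
    freq = allele_frequencies(counts)
    i, j = breeds.index(breed_a), breeds.index(breed_b)
    shared = np.sqrt(freq[i] * freq[j]).sum(axis=1)
    return float(1.0 - shared.mean())


def distance_matrix(
    blocks: BlockAlleleDataset,
    metric: str = "DEST",
    clamp: bool = True,
) -> pd.DataFrame:
    """Square symmetric breed-by-breed matrix for one metric.

    Negative estimator values (possible for the corrected D and G_ST) are
    clamped to zero unless ``clamp`` is off.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    breeds, counts, freq, ho = _count_tables(blocks)
    k = len(breeds)
    m = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        if metric == "NeiDA":
            v = 1.0 - np.sqrt(freq[i] * freq[j]).sum(axis=1).mean()
        else:
            hs, ht = _pair_components(counts, freq, ho, i, j)
            if metric == "GST":
                v = (ht - hs) / ht if ht > 0 else np.nan
            else:
                v = (ht - hs) / (1.0 - hs) * 2.0 if hs < 1.0 else 0.0
        if clamp and np.isfinite(v) and v < 0:
            v = 0.0
        m[i, j] = m[j, i] = v
    return pd.DataFrame(m, index=breeds, columns=breeds)


def mean_offdiagonal(matrix: pd.DataFrame) -> float:
    v = matrix.to_numpy()
    n = v.shape[0]
    return float(v[~np.eye(n, dtype=bool)].mean())


# ---------------------------------------------------------------------------
# PCA


def pca_scores(
    dataset: GenotypeDataset, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of frequency-standardised dosages.

    Dosages are centred by 2p and scaled by sqrt(p(1-p)); monomorphic
    SNPs are skipped.  Returns (scores frame with sample/breed columns,
    eigenvalues).
    """
    x = dataset.dosage()
    if np.isnan(x).any():
        raise ValueError("PCA requires complete genotypes")
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    x = x[:, poly]
    p = p[poly]
    z = (x - 2 * p) / np.sqrt(p * (1 - p))
    z -= z.mean(axis=0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    eig = (s[:k] ** 2) / (z.shape[0] - 1)
    df = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "breed", dataset.breeds)
    df.insert(0, "sample", dataset.sample_ids)
    return df, eig


# ---------------------------------------------------------------------------
# exports


def _check_square(matrix: pd.DataFrame) -> None:
    if list(matrix.index) != list(matrix.columns):
        raise ValueError("matrix must be square with matching labels")
    if len(set(matrix.index)) != len(matrix.index):
        raise ValueError("duplicate breed labels")
    if not np.allclose(matrix.to_numpy(), matrix.to_numpy().T):
        raise ValueError("matrix must be symmetric")


def _safe_label(label: str) -> str:
    out = "".join(c if (c.isalnum() or c in "._-") else "_" for c in str(label))
    return out[:50]


def write_phylip(matrix: pd.DataFrame, path: str | Path) -> None:
    """Square PHYLIP distance format."""
    _check_square(matrix)
    with open(path, "w") as fh:
        fh.write(f"{len(matrix)}\n")
        for label, row in matrix.iterrows():
            name = _safe_label(label).ljust(10)
            fh.write(name + " " + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return pd.DataFrame(rows, index=labels, columns=labels)


def write_nexus_distances(matrix: pd.DataFrame, path: str | Path) -> None:
    """NEXUS file with a TAXA and a DISTANCES block (square matrix)."""
    _check_square(matrix)
    labels = [_safe_label(b) for b in matrix.index]
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(labels)};\n  TAXLABELS\n")
        for lb in labels:
            fh.write(f"    {lb}\n")
        fh.write("  ;\nEND;\n\nBEGIN DISTANCES;\n")
        fh.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n  MATRIX\n")
        for lb, (_, row) in zip(labels, matrix.iterrows()):
            fh.write("    " + lb + " " + " ".join(f"{v:.6f}" for v in row) + "\n")
        fh.write("  ;\nEND;\n")


def export_distances(
    matrix: pd.DataFrame, out_prefix: str | Path, formats: tuple[str, ...] = ("phylip", "nexus")
) -> list[Path]:
    _check_square(matrix)
    written = []
    prefix = Path(out_prefix)
    if "phylip" in formats:
        p = prefix.with_suffix(".dist")
        write_phylip(matrix, p)
        written.append(p)
    if "nexus" in formats:
        p = prefix.with_suffix(".nex")
        write_nexus_distances(matrix, p)
        written.append(p)
    return written
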