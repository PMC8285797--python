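"""Unified additive relationship (UAR) matrix and relatedness pruning.

The UAR estimator standardises each SNP dosage by its current-sample
allele frequency: for samples j, k and SNP i with dosage x in {0,1,2} and
frequency p,

    A_jk = (1/M) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
    A_jj = 1 + (1/M) sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i))

over the M SNPs polymorphic in the current sample.  Expected values are
0.5 for parent-offspring and full-sib pairs and about -1/(n-1) for
unrelated animals (the centering of the estimator).

Pruning removes animals involved in within-breed pairs with UAR above a
threshold (default 0.25, half-way between half sibs and parent-offspring),
one animal per iteration, recomputing the matrix from the survivors each
time, until no within-breed pair exceeds the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeDataset


@dataclass
class UARMatrix:
    sample_ids: list[str]
    breeds: np.ndarray
    values: np.ndarray  # (n, n) float64, symmetric

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def of_pair(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def max_within_breed(self) -> float:
        """Largest within-breed off-diagonal entry (-inf if no such pair)."""
        best = -np.inf
        vals = self.values
        br = np.asarray(self.breeds)
        for b in dict.fromkeys(br):
            idx = np.flatnonzero(br == b)
            if len(idx) < 2:
                continue
            sub = vals[np.ix_(idx, idx)]
            off = sub[~np.eye(len(idx), dtype=bool)]
            best = max(best, float(off.max()))
        return best


def compute_uar(dataset: GenotypeDataset) -> UARMatrix:
    """Vectorised UAR over all samples, excluding sample-monomorphic SNPs."""
    if dataset.n_samples < 2:
        raise ValueError("need at least two samples")
    x = dataset.dosage()
    if np.isnan(x).any():
        raise ValueError("UAR requires complete genotypes")
    p = x.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic SNPs in the current sample")
    x = x[:, poly]
    p = p[poly]
    m = x.shape[1]
    denom = 2.0 * p * (1.0 - p)
    w = (x - 2.0 * p) / np.sqrt(denom)
    a = (w @ w.T) / m
    diag = 1.0 + ((x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom).mean(axis=1)
    np.fill_diagonal(a, diag)
    return UARMatrix(list(dataset.sample_ids), dataset.breeds.copy(), a)


def compute_uar_naive(dataset: GenotypeDataset) -> UARMatrix:
    """Double-loop reference implementation (slow; for verification)."""
    x = dataset.dosage()
    p = x.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    x = x[:, poly]
    p = p[poly]
    n, m = x.shape
    a = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            s = 0.0
            for i in range(m):
                d = 2.0 * p[i] * (1.0 - p[i])
                if j == k:
                    s += (x[j, i] ** 2 - (1 + 2 * p[i]) * x[j, i] + 2 * p[i] ** 2) / d
                else:
                    s += (x[j, i] - 2 * p[i]) * (x[k, i] - 2 * p[i]) / d
            a[j, k] = s / m + (1.0 if j == k else 0.0)
    return UARMatrix(list(dataset.sample_ids), dataset.breeds.copy(), a)


def _within_breed_pairs(uar: UARMatrix, threshold: float) -> list[tuple[int, int]]:
    pairs = []
    br = np.asarray(uar.breeds)
    vals = uar.values
    n = uar.n
    iu, ju = np.triu_indices(n, k=1)
    mask = (br[iu] == br[ju]) & (vals[iu, ju] > threshold)
    return list(zip(iu[mask].tolist(), ju[mask].tolist()))


def prune_related(
    dataset: GenotypeDataset,
    threshold: float = 0.25,
    max_iter: int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively remove one animal at a time until no within-breed pair
    exceeds ``threshold``.

    Selection rule per iteration: the animal with the most over-threshold
    within-breed partners; ties broken by highest mean within-breed UAR,
    then by lexicographically last sample id.  An animal is never removed
    if that would leave its breed with fewer than two animals.

    Returns the retained sample ids and a removal log
    (iteration, removed_id, breed, partner_id, uar_value).
    """
    current = dataset.copy()
    log: list[dict] = []
    it = 0
    while True:
        it += 1
        if max_iter is not None and it > max_iter:
            warnings.warn("prune_related reached max_iter before convergence")
            break
        uar = compute_uar(current)
        pairs = _within_breed_pairs(uar, threshold)
        if not pairs:
            break
        sizes = current.breed_sizes()
        degree = np.zeros(uar.n, dtype=int)
        for i, j in pairs:
            degree[i] += 1
            degree[j] += 1
        br = np.asarray(uar.breeds)
        candidates = [
            i
            for i in np.flatnonzero(degree > 0)
            if sizes[str(br[i])] > 2
        ]
        if not candidates:
            warnings.warn(
                "over-threshold pairs remain but removing would leave a breed "
                "with fewer than two animals; breed retained as-is"
            )
            break

        def mean_within(i: int) -> float:
            idx = np.flatnonzero((br == br[i]))
            idx = idx[idx != i]
            return float(uar.values[i, idx].mean()) if len(idx) else -np.inf

        candidates.sort(
            key=lambda i: (degree[i], mean_within(i), uar.sample_ids[i]),
            reverse=True,
        )
        worst = candidates[0]
        partner = max(
            (j for pair in pairs for j in pair if worst in pair and j != worst),
            key=lambda j: uar.values[worst, j],
        )
        log.append(
            {
                "iteration": it,
                "removed_id": uar.sample_ids[worst],
                "breed": str(br[worst]),
                "partner_id": uar.sample_ids[partner],
                "uar_value": float(uar.values[worst, partner]),
            }
        )
        keep = [s for k, s in enumerate(current.sample_ids) if k != worst]
        current = current.subset_samples(keep)
    return list(current.sample_ids), pd.DataFrame(
        log, columns=["iteration", "removed_id", "breed", "partner_id", "uar_value"]
    )
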