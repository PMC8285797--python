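"""Partition of allelic diversity and optimal-contribution pool design.

The allelic diversity of a set of breeds is split into a within-breed
component A_S (mean allele count per breed per block), a between-breed
component D_A (mean, over ordered breed pairs including i = j, of the
number of alleles present in breed i but absent from breed j) and a total
A_T (mean pooled-pair allele count over the same ordered pairs), which
satisfy A_T = A_S + D_A exactly.  Each breed's contribution is the
percent change in each component when the breed is removed; a positive
value means diversity is lost on removal.

The pool optimizer allocates a fixed number of animals across breeds to
maximise the expected number of distinct block alleles

    E[A](n) = sum_blocks sum_alleles [1 - prod_i (1 - p_ali)^(2 n_i)]

under binomial (with-replacement) sampling of gene copies, using greedy
unit allocation followed by pairwise-swap hill climbing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import BlockAlleleDataset
from .diversity import allele_counts, allele_frequencies


@dataclass
class AllelicPartition:
    a_s: float
    d_a: float
    a_t: float
    breeds: list[str]

    def as_dict(self) -> dict[str, float]:
        return {"A_S": self.a_s, "D_A": self.d_a, "A_T": self.a_t}


def partition_from_counts(counts: np.ndarray, breeds: list[str]) -> AllelicPartition:
    """Partition A_T = A_S + D_A from a (K, B, A) presence/count array."""
    present = counts > 0
    k = len(breeds)
    if k == 1:
        warnings.warn("single breed: degenerate partition with D_A = 0")
    a_i = present.sum(axis=2)  # (K, B) alleles per breed per block
    a_s = float(a_i.mean(axis=1).mean())
    # d[i, j] = mean over blocks of |alleles in i and not in j|
    d = np.zeros((k, k))
    t = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            only_i = present[i] & ~present[j]
            d[i, j] = only_i.sum(axis=1).mean()
            t[i, j] = (present[i] | present[j]).sum(axis=1).mean()
    d_a = float(d.mean())
    a_t = float(t.mean())
    return AllelicPartition(a_s, d_a, a_t, list(breeds))


def allelic_partition(blocks: BlockAlleleDataset) -> AllelicPartition:
    breeds, counts = allele_counts(blocks)
    return partition_from_counts(counts, breeds)


def breed_contributions(blocks: BlockAlleleDataset) -> pd.DataFrame:
    """Leave-one-breed-out percent change of A_S, D_A and A_T.

    Positive entries mean the component drops when the breed is removed
    (the breed contributes that share of diversity).
    """
    breeds, counts = allele_counts(blocks)
    if len(breeds) < 3:
        raise ValueError("breed contributions need at least three breeds")
    full = partition_from_counts(counts, breeds)
    rows = []
    for k, b in enumerate(breeds):
        rest = [i for i in range(len(breeds)) if i != k]
        part = partition_from_counts(counts[rest], [breeds[i] for i in rest])
        rows.append(
            {
                "breed": b,
                "dA_S_pct": 100.0 * (full.a_s - part.a_s) / full.a_s,
                "dD_A_pct": 100.0 * (full.d_a - part.d_a) / full.d_a
                if full.d_a != 0
                else np.nan,
                "dA_T_pct": 100.0 * (full.a_t - part.a_t) / full.a_t,
            }
        )
    return pd.DataFrame(rows).set_index("breed")


# ---------------------------------------------------------------------------
# pool optimization


@dataclass
class PoolSolution:
    counts: pd.Series  # breed -> animals contributed
    expected_alleles: float
    trace: list[dict] = field(default_factory=list)

    @property
    def pool_size(self) -> int:
        return int(self.counts.sum())

    def percentages(self) -> pd.Series:
        return 100.0 * self.counts / self.counts.sum()


def expected_alleles(freq: np.ndarray, n: np.ndarray) -> float:
    """E[A] for contribution vector ``n`` given per-breed allele
    frequencies ``freq`` of shape (K, B, A)."""
    log_miss = np.log1p(-np.minimum(freq, 1.0 - 1e-12))
    s = np.tensordot(2.0 * np.asarray(n, dtype=float), log_miss, axes=(0, 0))
    present_any = (freq > 0).any(axis=0)
    return float((1.0 - np.exp(s))[present_any].sum())


def optimize_pool(
    blocks: BlockAlleleDataset,
    pool_size: int = 1000,
    seed: int = 0,
    max_swap_passes: int = 100,
) -> PoolSolution:
    """Greedy unit allocation plus pairwise-swap hill climbing.

    Deterministic for a given dataset (ties broken by breed order); the
    seed only controls the optional randomised restart order and is kept
    for interface stability.
    """
    breeds, counts = allele_counts(blocks)
    freq = allele_frequencies(counts)
    k = len(breeds)
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    log_miss = np.log1p(-np.minimum(freq, 1.0 - 1e-12))  # (K, B, A)
    present_any = (freq > 0).any(axis=0)
    flat = log_miss[:, present_any]  # (K, M)
    n = np.zeros(k, dtype=int)
    s = np.zeros(flat.shape[1])  # running sum of 2 n_i log(1 - p_i)
    unit_gain = (1.0 - np.exp(2.0 * flat)).T  # (M, K), fixed per-allele factors
    trace: list[dict] = []
    for step in range(pool_size):
        miss = np.exp(s)
        gains = miss @ unit_gain  # gain of one more animal from each breed
        best = int(np.argmax(gains))
        n[best] += 1
        s += 2.0 * flat[best]
        trace.append({"step": step + 1, "breed": breeds[best], "gain": float(gains[best])})
    value = float((1.0 - np.exp(s)).sum())
    # pairwise-swap hill climbing
    for _ in range(max_swap_passes):
        improved = False
        for i in range(k):
            if n[i] == 0:
                continue
            base = s - 2.0 * flat[i]
            for j in range(k):
                if j == i:
                    continue
                cand = base + 2.0 * flat[j]
                v = float((1.0 - np.exp(cand)).sum())
                if v > value + 1e-12:
                    n[i] -= 1
                    n[j] += 1
                    s = cand
                    value = v
                    improved = True
                    trace.append(
                        {"step": -1, "breed": f"{breeds[i]}->{breeds[j]}", "gain": v}
                    )
                    break
            if improved:
                break
        if not improved:
            break
    return PoolSolution(pd.Series(n, index=breeds, name="count"), value, trace)


def exhaustive_pool(blocks: BlockAlleleDataset, pool_size: int) -> PoolSolution:
    """Exact optimum by enumeration of all compositions (small instances only)."""
    breeds, counts = allele_counts(blocks)
    freq = allele_frequencies(counts)
    k = len(breeds)
    best_n, best_v = None, -np.inf

    def rec(prefix: list[int], remaining: int):
        nonlocal best_n, best_v
        if len(prefix) == k - 1:
            n = np.array(prefix + [remaining])
            v = expected_alleles(freq, n)
            if v > best_v + 1e-12:
                best_v, best_n = v, n
            return
        for c in range(remaining + 1):
            rec(prefix + [c], remaining - c)

    rec([], pool_size)
    return PoolSolution(pd.Series(best_n, index=breeds, name="count"), float(best_v))


def random_pool_baseline(
    blocks: BlockAlleleDataset, pool_size: int, n_draws: int = 1000, seed: int = 0
) -> float:
    """Best E[A] over random compositions (multinomial over breeds)."""
    breeds, counts = allele_counts(blocks)
    freq = allele_frequencies(counts)
    rng = np.random.default_rng(seed)
    best = -np.inf
    for _ in range(n_draws):
        n = rng.multinomial(pool_size, np.full(len(breeds), 1.0 / len(breeds)))
        best = max(best, expected_alleles(freq, n))
    return float(best)
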