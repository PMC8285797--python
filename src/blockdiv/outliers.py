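"""Per-breed multivariate admixture-outlier detection (step one of the
two-step dataset optimization).

Each animal of a focal breed is summarised by four admixture signatures:

``f1``
    mean UAR with own-breed animals (self excluded) — admixed animals are
    less related to their nominal breed;
``f2``
    strength of the strongest cross-breed relationships: the mean of the
    top ``F2_TOP_K`` UAR values with other-breed animals.  Averaging the
    top few links keeps the admixture signal (an admixed animal is
    elevated against many donor-breed animals) while avoiding the
    heavy-tailed null distribution of a plain maximum;
``f3``
    foreign-allele proportion: the fraction of the animal's block-allele
    copies absent from own-breed animals (self excluded) but present in at
    least one other breed;
``f4``
    number of other-breed animals with UAR above ``link_threshold``
    (network links to foreign animals).

Features are robustly z-scored (median / scaled MAD) per breed and fed to
a minimum-covariance-determinant (MCD) estimator.  Because MCD distances
are strongly inflated at the sample sizes typical of one breed (tens of
animals), all cutoffs are referred to a simulated Gaussian null at the
same (n, d) rather than to the asymptotic chi-square distribution (which
remains available via ``cutoff_method="chi2"``).

Several flagging rules are provided.  The plain detector flags every
animal whose squared robust distance exceeds the null (1 - alpha)
quantile; it has marginal false-flag rate alpha by construction and
suits one-shot screening.  The iterative dataset-formation loop instead
controls the family-wise rate per breed: it flags only distances beyond
the null (1 - alpha) quantile of the per-breed *maximum* distance, so a
breed without genuine outliers flags anything with probability about
alpha and the remove-and-repeat loop terminates without eroding clean
breeds.  Admixed animals sit orders of magnitude beyond either cutoff,
so all rules recover them; an adjusted-quantile rule (flag the tail only
where the empirical distance distribution exceeds the null by more than
a critical sampling fluctuation) is also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import chi2, median_abs_deviation
from sklearn.covariance import MinCovDet

from .blocks import MISSING_CODE, BlockAlleleDataset, allele_count_array
from .core import GenotypeDataset
from .relatedness import UARMatrix, compute_uar

FEATURES = ["f1", "f2", "f3", "f4"]

LINK_THRESHOLD_DEFAULT = 0.1
ALPHA_DEFAULT = 0.025
F2_TOP_K = 5
SUPPORT_FRACTION = 0.75
MIN_FEATURE_SAMPLE = 10

#: replicates used to simulate the null distance distribution per (n, d)
NULL_REPLICATES = 100


def compute_outlier_features(
    dataset: GenotypeDataset,
    uar: UARMatrix,
    blocks: BlockAlleleDataset,
    breed: str,
    link_threshold: float = LINK_THRESHOLD_DEFAULT,
    standardize: bool = True,
) -> pd.DataFrame:
    """Admixture-signature feature matrix for every animal of ``breed``.

    Returns a data frame indexed by sample id with (a subset of) columns
    f1..f4; columns whose MAD is zero within the breed are dropped with a
    warning when ``standardize`` is on.
    """
    br = np.asarray(uar.breeds)
    own = np.flatnonzero(br == breed)
    other = np.flatnonzero(br != breed)
    if len(own) < MIN_FEATURE_SAMPLE:
        raise ValueError(
            f"breed {breed!r} has {len(own)} animals; need >= {MIN_FEATURE_SAMPLE}"
        )
    if len(other) == 0:
        raise ValueError("outlier features need at least one other breed")
    vals = uar.values
    f1 = np.array(
        [vals[i, own[own != i]].mean() for i in own]
    )
    cross = vals[np.ix_(own, other)]
    k = min(F2_TOP_K, cross.shape[1])
    f2 = np.partition(cross, -k, axis=1)[:, -k:].mean(axis=1)
    f4 = (cross > link_threshold).sum(axis=1).astype(float)
    f3 = _foreign_allele_proportion(blocks, breed)
    feat = pd.DataFrame(
        {"f1": f1, "f2": f2, "f3": f3, "f4": f4},
        index=[uar.sample_ids[i] for i in own],
    )
    if standardize:
        feat = robust_standardize(feat)
    return feat


def _foreign_allele_proportion(blocks: BlockAlleleDataset, breed: str) -> np.ndarray:
    """f3 per own-breed animal: fraction of its block-allele copies that are
    absent among own-breed animals (self excluded) and present elsewhere."""
    breeds_list, counts = allele_count_array(blocks)
    k = breeds_list.index(breed)
    own_counts = counts[k]  # (n_blocks, 16)
    other_present = (counts.sum(axis=0) - own_counts) > 0
    own_rows = np.flatnonzero(np.asarray(blocks.breeds) == breed)
    out = np.empty(len(own_rows))
    n_blocks = blocks.n_blocks
    block_idx = np.arange(n_blocks)
    for t, i in enumerate(own_rows):
        c1 = blocks.codes[2 * i]
        c2 = blocks.codes[2 * i + 1]
        total = 0
        foreign = 0
        for c in (c1, c2):
            valid = c != MISSING_CODE
            bi = block_idx[valid]
            cc = c[valid]
            # copies of this allele held by the animal itself
            self_copies = (c1[valid] == cc).astype(np.int32) + (
                c2[valid] == cc
            ).astype(np.int32)
            absent_own = own_counts[bi, cc] - self_copies == 0
            foreign += int((absent_own & other_present[bi, cc]).sum())
            total += int(valid.sum())
        out[t] = foreign / total if total else 0.0
    return out


def robust_standardize(feat: pd.DataFrame) -> pd.DataFrame:
    """Center by median, scale by normal-consistent MAD; drop zero-MAD columns."""
    kept = {}
    for col in feat.columns:
        x = feat[col].to_numpy(dtype=float)
        mad = median_abs_deviation(x, scale="normal")
        if mad == 0:
            warnings.warn(f"feature {col} has zero MAD in this breed; dropped")
            continue
        kept[col] = (x - np.median(x)) / mad
    return pd.DataFrame(kept, index=feat.index)


@lru_cache(maxsize=256)
def _null_distances(
    n: int, d: int, replicates: int = NULL_REPLICATES
) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated robust distances under a Gaussian null of the same
    sample size and dimension: (sorted pooled distances, per-replicate
    maxima).

    Deterministic: the null stream is seeded from (n, d) only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([97, n, d]))
    pooled = []
    maxima = []
    for r in range(replicates):
        x = rng.standard_normal((n, d))
        d2 = _robust_distances(x, random_state=r)
        pooled.append(d2)
        maxima.append(d2.max())
    return np.sort(np.concatenate(pooled)), np.asarray(maxima)


def _null_pool(n: int, d: int) -> np.ndarray:
    return _null_distances(n, d)[0]


def _null_cutoff(n: int, d: int, alpha: float) -> float:
    """(1 - alpha) quantile of the simulated null distances (per-animal)."""
    return float(np.quantile(_null_pool(n, d), 1.0 - alpha))


def _maxnull_cutoff(n: int, d: int, alpha: float) -> float:
    """(1 - alpha) quantile of the null per-sample maximum distance:
    a clean breed exceeds it with probability about alpha (family-wise)."""
    return float(np.quantile(_null_distances(n, d)[1], 1.0 - alpha))


#: cap on the estimated outlier fraction (MCD support is 75%)
MAX_OUTLIER_FRACTION = 0.25


def _adjusted_cutoff(d2: np.ndarray, n: int, d: int, alpha: float) -> float:
    """Adjusted-quantile cutoff: flag the tail only where the empirical
    distance distribution carries more mass than the simulated null.

    The excess G_null(u) - G_emp(u) is evaluated over the tail region
    u >= null (1 - alpha) quantile; if its supremum stays below the
    critical fluctuation (0.24 - 0.003 d) / sqrt(n) the breed is declared
    outlier-free (cutoff = +inf), otherwise the cutoff is placed at the
    order statistic where the supremum is attained.
    """
    null = _null_pool(n, d)
    delta = float(np.quantile(null, 1.0 - alpha))
    s = np.sort(d2)
    m = len(s)
    g_null = np.searchsorted(null, s, side="right") / len(null)
    g_emp = np.arange(1, m + 1) / m
    excess = g_null - g_emp
    region = s >= delta
    if not region.any():
        return np.inf
    p_crit = (0.24 - 0.003 * min(d, 10)) / np.sqrt(m)
    # candidate cutoffs: the tail order statistics and delta itself
    first = int(np.searchsorted(s, delta, side="left"))
    excess_delta = (1.0 - alpha) - first / m
    alpha_n = max(float(excess[region].max()), excess_delta)
    if alpha_n <= p_crit:
        return np.inf
    if excess_delta >= float(excess[region].max()):
        k = m - first
    else:
        i_star = np.flatnonzero(region)[int(np.argmax(excess[region]))]
        k = m - (i_star + 1)
    k = min(k, int(MAX_OUTLIER_FRACTION * m))
    if k == 0:
        return np.inf
    return float(s[m - k - 1])


def _robust_distances(x: np.ndarray, random_state: int = 0) -> np.ndarray:
    """Squared MCD Mahalanobis distances, median-rescaled for consistency."""
    n, d = x.shape
    mcd = MinCovDet(support_fraction=SUPPORT_FRACTION, random_state=random_state).fit(x)
    if np.linalg.matrix_rank(mcd.covariance_) < d:
        raise np.linalg.LinAlgError("singular robust scatter")
    d2 = mcd.mahalanobis(x)
    med = np.median(d2)
    if med <= 0:
        raise np.linalg.LinAlgError("degenerate robust distances")
    return d2 * (chi2.ppf(0.5, d) / med)


@dataclass
class OutlierResult:
    table: pd.DataFrame  # index: sample id; columns: distance, cutoff, flagged
    cutoff: float
    fallback: bool = False

    @property
    def flagged(self) -> list[str]:
        return self.table.index[self.table["flagged"]].tolist()


def detect_outliers(
    features: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    cutoff_method: str = "simulated",
    random_state: int = 0,
) -> OutlierResult:
    """Flag animals whose robust squared distance exceeds the cutoff.

    ``cutoff_method="simulated"`` (default) places the cutoff at the
    (1 - alpha) quantile of a Gaussian null at the same (n, d);
    ``"maxnull"`` at the (1 - alpha) quantile of the null per-sample
    maximum (family-wise; the default inside the removal loop);
    ``"adaptive"`` uses the adjusted-quantile rule against the same
    null; ``"chi2"`` the asymptotic chi-square quantile.  Falls back to
    a univariate robust z-rule (|z| > 3.5 in any feature) if the robust
    scatter is singular.
    """
    x = features.to_numpy(dtype=float)
    n, d = x.shape
    if n < d + 2:
        raise ValueError(f"insufficient sample: n={n} < d+2={d + 2}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d2 = _robust_distances(x, random_state=random_state)
        if cutoff_method == "chi2":
            cutoff = float(chi2.ppf(1.0 - alpha, d))
        elif cutoff_method == "simulated":
            cutoff = _null_cutoff(n, d, alpha)
        elif cutoff_method == "adaptive":
            cutoff = _adjusted_cutoff(d2, n, d, alpha)
        elif cutoff_method == "maxnull":
            cutoff = _maxnull_cutoff(n, d, alpha)
        else:
            raise ValueError(f"unknown cutoff_method {cutoff_method!r}")
        flagged = d2 > cutoff
        table = pd.DataFrame(
            {"distance": d2, "cutoff": cutoff, "flagged": flagged}, index=features.index
        )
        return OutlierResult(table, cutoff)
    except np.linalg.LinAlgError:
        warnings.warn("singular robust scatter; falling back to univariate robust z")
        z = np.abs(x)  # features are already robust z-scores
        dist = z.max(axis=1)
        flagged = dist > 3.5
        table = pd.DataFrame(
            {"distance": dist, "cutoff": 3.5, "flagged": flagged}, index=features.index
        )
        return OutlierResult(table, 3.5, fallback=True)


def iterate_outlier_removal(
    dataset: GenotypeDataset,
    blocks_builder,
    breeds: list[str] | None = None,
    alpha: float = ALPHA_DEFAULT,
    min_breed_n: int = 14,
    max_iter: int = 20,
    link_threshold: float = LINK_THRESHOLD_DEFAULT,
    cutoff_method: str = "maxnull",
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Iterate detection and removal per breed until no outliers remain.

    ``blocks_builder`` maps a :class:`GenotypeDataset` to a
    :class:`BlockAlleleDataset` (UAR and block alleles are recomputed from
    the survivors each iteration).  Each breed iterates until its first
    flag-free round; per breed and iteration at most ``size - min_breed_n``
    animals are removed (worst distances first), and a breed capped this
    way is frozen for later iterations.

    Returns retained sample ids and a log
    (breed, iteration, sample_id, distance, cutoff).
    """
    current = dataset.copy()
    if breeds is None:
        breeds = current.breed_names()
    # a breed is done after its first iteration without flags (or when
    # capped at the inclusion minimum); other breeds' earlier removals
    # feed into its features through the shared UAR and block data
    frozen: set[str] = set()
    log: list[dict] = []
    for it in range(1, max_iter + 1):
        uar = compute_uar(current)
        blk = blocks_builder(current)
        removals: list[str] = []
        sizes = current.breed_sizes()
        for breed in breeds:
            if breed in frozen or breed not in sizes.index:
                continue
            feat = compute_outlier_features(
                current, uar, blk, breed, link_threshold=link_threshold
            )
            if feat.shape[1] == 0:
                continue
            res = detect_outliers(
                feat,
                alpha=alpha,
                cutoff_method=cutoff_method,
                random_state=seed + it,
            )
            flagged = res.table[res.table["flagged"]].sort_values(
                "distance", ascending=False
            )
            if flagged.empty:
                frozen.add(breed)
                continue
            budget = int(sizes[breed]) - min_breed_n
            if budget <= 0:
                warnings.warn(
                    f"breed {breed} at inclusion minimum; outlier flags ignored"
                )
                frozen.add(breed)
                continue
            take = flagged.head(budget)
            if len(take) < len(flagged):
                warnings.warn(
                    f"breed {breed} capped at min_breed_n={min_breed_n}; "
                    "worst outliers removed, breed frozen"
                )
                frozen.add(breed)
            for sid, row in take.iterrows():
                log.append(
                    {
                        "breed": breed,
                        "iteration": it,
                        "sample_id": sid,
                        "distance": float(row["distance"]),
                        "cutoff": float(row["cutoff"]),
                    }
                )
                removals.append(sid)
        if not removals:
            break
        keep = [s for s in current.sample_ids if s not in set(removals)]
        current = current.subset_samples(keep)
    else:
        warnings.warn("outlier iteration reached max_iter before convergence")
    return list(current.sample_ids), pd.DataFrame(
        log, columns=["breed", "iteration", "sample_id", "distance", "cutoff"]
    )
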