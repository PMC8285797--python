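"""Synthetic multi-breed SNP panels with known admixture and relatedness.

Breeds are drifted independently from a common ancestral gene pool under
the Balding--Nichols model: for ancestral frequency ``p`` and drift
parameter ``F`` (the expected F_ST of the breed against the ancestral
pool), the breed frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), so that
``E[p_breed] = p`` and ``Var(p_breed) = F p (1-p)``.

Haplotypes are drawn independently per SNP (no background linkage
disequilibrium); the only long-range haplotype sharing in the data comes
from injected relatives, whose gametes are formed by recombination from
parental chromosomes.  Admixed animals draw each gamete's allele from the
donor breed's frequency with probability ``alpha`` and from the recipient
breed otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeDataset, GroundTruth, make_snp_map

#: base pairs per expected crossover (Haldane-style, ~1 per 100 Mb)
BP_PER_CROSSOVER = 100_000_000


@dataclass
class AdmixtureEvent:
    recipient: str
    donor: str
    alpha: float
    n_animals: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"admixture proportion must be in [0, 1], got {self.alpha}")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


@dataclass
class RelativePairSpec:
    breed: str
    relationship: str  # "parent-offspring" | "full-sib"
    n_pairs: int = 1

    def __post_init__(self) -> None:
        if self.relationship not in ("parent-offspring", "full-sib"):
            raise ValueError(f"unknown relationship {self.relationship!r}")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic panel.

    Defaults describe the standard scenario used throughout the test
    suite: 10 breeds of 30 animals drifted at F_ST = 0.1, 10,000 SNPs at a
    mean spacing of 60 kb over 29 autosomes.  Inter-SNP distances are
    exponential by default (Poisson marker placement), which produces the
    mixture of sub-50 kb and larger gaps that the block builder needs;
    ``spacing_model="uniform_jitter"`` lays SNPs on a near-regular grid
    instead.
    """

    n_breeds: int = 10
    n_per_breed: int = 30
    fst: float | list[float] = 0.1
    n_snps: int = 10_000
    spacing_bp: int = 60_000
    n_chromosomes: int = 29
    admixture_events: list[AdmixtureEvent] = field(default_factory=list)
    relative_pairs: list[RelativePairSpec] = field(default_factory=list)
    seed: int = 0
    spacing_model: str = "exponential"  # or "uniform_jitter"
    jitter_frac: float = 0.10

    def __post_init__(self) -> None:
        for name in ("n_breeds", "n_per_breed", "n_snps", "spacing_bp", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for f in self.fst_per_breed():
            if not 0.0 < f < 1.0:
                raise ValueError(f"fst must lie in (0, 1), got {f}")
        if self.spacing_model not in ("exponential", "uniform_jitter"):
            raise ValueError(f"unknown spacing_model {self.spacing_model!r}")

    def fst_per_breed(self) -> list[float]:
        if isinstance(self.fst, (int, float)):
            return [float(self.fst)] * self.n_breeds
        if len(self.fst) != self.n_breeds:
            raise ValueError("fst list length must equal n_breeds")
        return [float(f) for f in self.fst]

    def breed_names(self) -> list[str]:
        return [f"B{i + 1:02d}" for i in range(self.n_breeds)]


@dataclass
class BreedFrequencies:
    """Ancestral and per-breed alternate-allele frequencies."""

    breeds: list[str]
    ancestral: np.ndarray  # (n_snps,)
    freqs: np.ndarray  # (n_breeds, n_snps)

    def of(self, breed: str) -> np.ndarray:
        return self.freqs[self.breeds.index(breed)]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage so injections do not
    # perturb the base draw
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def simulate_frequencies(config: SimulationConfig) -> BreedFrequencies:
    """Draw ancestral and Balding--Nichols per-breed allele frequencies."""
    rng = _rng(config, 0)
    p = rng.uniform(0.05, 0.95, size=config.n_snps)
    freqs = np.empty((config.n_breeds, config.n_snps))
    for k, f in enumerate(config.fst_per_breed()):
        a = p * (1.0 - f) / f
        b = (1.0 - p) * (1.0 - f) / f
        freqs[k] = rng.beta(a, b)
    return BreedFrequencies(config.breed_names(), p, freqs)


def _layout_positions(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place SNPs on autosomes; returns SNP map."""
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    chroms: list[str] = []
    pos: list[np.ndarray] = []
    for c, m in enumerate(per_chrom, start=1):
        if m == 0:
            continue
        if config.spacing_model == "exponential":
            gaps = rng.exponential(config.spacing_bp, size=m)
        else:
            lo = config.spacing_bp * (1.0 - config.jitter_frac)
            hi = config.spacing_bp * (1.0 + config.jitter_frac)
            gaps = rng.uniform(lo, hi, size=m)
        p = np.maximum(1, np.round(gaps)).astype(np.int64).cumsum()
        # enforce strict increase after rounding
        p = np.maximum.accumulate(p + np.arange(m))
        chroms.extend([str(c)] * m)
        pos.append(p)
    positions = np.concatenate(pos)
    ids = [f"snp{i + 1}" for i in range(config.n_snps)]
    return make_snp_map(ids, chroms, positions)


def simulate_genotypes(
    freqs: BreedFrequencies, config: SimulationConfig
) -> tuple[GenotypeDataset, GroundTruth]:
    """Draw phased haplotypes for every breed and inject admixture/relatives."""
    rng = _rng(config, 1)
    snps = _layout_positions(config, rng)
    n_total = config.n_breeds * config.n_per_breed
    hap = np.empty((2 * n_total, config.n_snps), dtype=np.int8)
    sample_ids: list[str] = []
    breeds: list[str] = []
    for k, breed in enumerate(freqs.breeds):
        pk = freqs.freqs[k]
        draws = rng.random((2 * config.n_per_breed, config.n_snps)) < pk
        r0 = 2 * k * config.n_per_breed
        hap[r0 : r0 + 2 * config.n_per_breed] = draws.astype(np.int8)
        for j in range(config.n_per_breed):
            sample_ids.append(f"{breed}_{j + 1:03d}")
            breeds.append(breed)
    ds = GenotypeDataset(sample_ids, np.array(breeds, dtype=object), snps, hap, phased=True)
    truth = GroundTruth.purebred(sample_ids, breeds)
    rng_adm = _rng(config, 2)
    for event in config.admixture_events:
        inject_admixed(ds, truth, freqs, event, rng_adm)
    rng_rel = _rng(config, 3)
    for spec in config.relative_pairs:
        inject_relatives(ds, truth, freqs, spec, rng_rel)
    return ds, truth


def inject_admixed(
    dataset: GenotypeDataset,
    truth: GroundTruth,
    freqs: BreedFrequencies,
    event: AdmixtureEvent,
    rng: np.random.Generator,
) -> list[str]:
    """Overwrite purebred recipients with admixed genomes; returns their ids."""
    if event.recipient not in freqs.breeds:
        raise ValueError(f"unknown recipient breed {event.recipient!r}")
    if event.donor not in freqs.breeds:
        raise ValueError(f"unknown donor breed {event.donor!r}")
    candidates = [
        s
        for s in dataset.samples_of(event.recipient)
        if truth.table.loc[truth.table["sample_id"] == s, "label"].item() == "purebred"
    ]
    if len(candidates) < event.n_animals:
        raise ValueError(f"not enough purebred animals left in {event.recipient}")
    chosen = candidates[: event.n_animals]
    p_r = freqs.of(event.recipient)
    p_d = freqs.of(event.donor)
    for sid in chosen:
        i = dataset.index_of(sid)
        from_donor = rng.random((2, dataset.n_snps)) < event.alpha
        p_mix = np.where(from_donor, p_d, p_r)
        dataset.haplotypes[2 * i : 2 * i + 2] = (
            rng.random((2, dataset.n_snps)) < p_mix
        ).astype(np.int8)
        truth.set_admixed(sid, event.donor, event.alpha)
    return chosen


def _gamete(
    parent_hap: np.ndarray, snps: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete from a parent's two haplotypes."""
    out = np.empty(parent_hap.shape[1], dtype=np.int8)
    for _, grp in snps.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        length = int(pos[-1] - pos[0]) + 1
        n_x = rng.poisson(length / BP_PER_CROSSOVER)
        cuts = np.sort(rng.uniform(pos[0], pos[-1], size=n_x))
        seg = np.searchsorted(cuts, pos)  # segment index per SNP
        which = (seg + rng.integers(2)) % 2
        out[idx] = parent_hap[which, idx]
    return out


def inject_relatives(
    dataset: GenotypeDataset,
    truth: GroundTruth,
    freqs: BreedFrequencies,
    spec: RelativePairSpec,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Replace purebred animals with members of close-relative pairs.

    Parent-offspring: one existing animal is the in-panel parent; a hidden
    mate is drawn from the breed's frequencies, and the offspring replaces
    another purebred slot.  Full sibs: two hidden parents produce two
    offspring that replace two purebred slots.  Either way each injected
    pair shares an expected UAR of 0.5 and is unrelated to everyone else,
    so pairs are disjoint.
    """
    if spec.breed not in freqs.breeds:
        raise ValueError(f"unknown breed {spec.breed!r}")
    pairs: list[tuple[str, str]] = []
    p = freqs.of(spec.breed)
    for _ in range(spec.n_pairs):
        candidates = [
            s
            for s in dataset.samples_of(spec.breed)
            if truth.table.loc[truth.table["sample_id"] == s, "label"].item() == "purebred"
        ]
        need = 1 if spec.relationship == "parent-offspring" else 2
        if len(candidates) < need + (1 if spec.relationship == "parent-offspring" else 0):
            raise ValueError(f"not enough purebred animals left in {spec.breed}")
        if spec.relationship == "parent-offspring":
            parent_id, child_slot = candidates[0], candidates[1]
            i_par = dataset.index_of(parent_id)
            parent_hap = dataset.haplotypes[2 * i_par : 2 * i_par + 2]
            mate_hap = (rng.random((2, dataset.n_snps)) < p).astype(np.int8)
            child = np.stack(
                [
                    _gamete(parent_hap, dataset.snps, rng),
                    _gamete(mate_hap, dataset.snps, rng),
                ]
            )
            i_child = dataset.index_of(child_slot)
            dataset.haplotypes[2 * i_child : 2 * i_child + 2] = child
            truth.set_relative(parent_id, child_slot, 0.5)
            truth.set_relative(child_slot, parent_id, 0.5)
            pairs.append((parent_id, child_slot))
        else:
            slot_a, slot_b = candidates[0], candidates[1]
            sire = (rng.random((2, dataset.n_snps)) < p).astype(np.int8)
            dam = (rng.random((2, dataset.n_snps)) < p).astype(np.int8)
            for slot in (slot_a, slot_b):
                child = np.stack(
                    [
                        _gamete(sire, dataset.snps, rng),
                        _gamete(dam, dataset.snps, rng),
                    ]
                )
                i = dataset.index_of(slot)
                dataset.haplotypes[2 * i : 2 * i + 2] = child
            truth.set_relative(slot_a, slot_b, 0.5)
            truth.set_relative(slot_b, slot_a, 0.5)
            pairs.append((slot_a, slot_b))
    return pairs


def simulate(config: SimulationConfig) -> tuple[GenotypeDataset, GroundTruth]:
    """Convenience wrapper: frequencies + genotypes + injections in one call."""
    freqs = simulate_frequencies(config)
    return simulate_genotypes(freqs, config)


def standard_scenario(
    seed: int,
    admixture: bool = True,
    relatives: bool = False,
    alpha: float = 0.5,
    admixed_per_breed: int = 3,
    n_relative_pairs: int = 5,
    **overrides,
) -> SimulationConfig:
    """The default study conditions: 10 breeds x 30 animals, F_ST 0.1,
    10,000 SNPs; 10% of each breed admixed at ``alpha`` from the next
    breed in cyclic order, optionally with disjoint parent-offspring pairs.
    """
    cfg = SimulationConfig(seed=seed, **overrides)
    names = cfg.breed_names()
    if admixture:
        cfg.admixture_events = [
            AdmixtureEvent(names[i], names[(i + 1) % len(names)], alpha, admixed_per_breed)
            for i in range(len(names))
        ]
    if relatives:
        cfg.relative_pairs = [
            RelativePairSpec(names[i % len(names)], "parent-offspring", 1)
            for i in range(n_relative_pairs)
        ]
    return cfg
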