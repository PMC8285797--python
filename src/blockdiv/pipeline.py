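"""One-step and two-step dataset optimization, and the full report bundle.

The one-step procedure prunes close relatives only; the two-step
procedure first excludes admixed/mislabelled animals per breed by
multivariate outlier analysis and then prunes relatives among the
survivors.  Admixed-but-unrelated animals survive the one-step route and
inflate within-breed diversity while deflating between-breed
differentiation; the two-step route removes them, which is the
methodological point the stage-difference tables expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import blocks as blocks_mod
from . import differentiation, diversity, metapop, outliers, relatedness
from .core import GenotypeDataset

STAGES = ("Init", "OneStep", "TwoStep")


@dataclass
class DatasetStage:
    label: str
    dataset: GenotypeDataset
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["stage", "op", "sample_id", "breed", "detail"]
        )
    )

    @property
    def retained(self) -> list[str]:
        return list(self.dataset.sample_ids)


def blocks_builder(
    block_size: int = 4, max_gap: int = 50_000, max_span: int = 150_000
):
    """A callable mapping a dataset to its block-allele encoding, with the
    block constraints fixed once for the whole pipeline run."""

    def build(ds: GenotypeDataset) -> blocks_mod.BlockAlleleDataset:
        bm = blocks_mod.build_block_map(
            ds.snps, block_size=block_size, max_gap=max_gap, max_span=max_span
        )
        return blocks_mod.encode_block_alleles(ds, bm)

    return build


_blocks_builder = blocks_builder


def one_step(
    dataset: GenotypeDataset, uar_threshold: float = 0.25
) -> DatasetStage:
    """Relatedness pruning only (the conventional route)."""
    retained, log = relatedness.prune_related(dataset, threshold=uar_threshold)
    prov = pd.DataFrame(
        {
            "stage": "OneStep",
            "op": "prune_related",
            "sample_id": log["removed_id"],
            "breed": log["breed"],
            "detail": [
                f"UAR {v:.3f} with {p}"
                for v, p in zip(log["uar_value"], log["partner_id"])
            ],
        }
    )
    return DatasetStage("OneStep", dataset.subset_samples(retained), prov)


def two_step(
    dataset: GenotypeDataset,
    uar_threshold: float = 0.25,
    alpha: float = outliers.ALPHA_DEFAULT,
    min_breed_n: int = 14,
    link_threshold: float = outliers.LINK_THRESHOLD_DEFAULT,
    seed: int = 0,
    block_kwargs: dict | None = None,
) -> DatasetStage:
    """Outlier exclusion per breed, then relatedness pruning."""
    builder = blocks_builder(**(block_kwargs or {}))
    survivors, outlier_log = outliers.iterate_outlier_removal(
        dataset,
        builder,
        alpha=alpha,
        min_breed_n=min_breed_n,
        link_threshold=link_threshold,
        seed=seed,
    )
    after_outliers = dataset.subset_samples(survivors)
    retained, prune_log = relatedness.prune_related(
        after_outliers, threshold=uar_threshold
    )
    prov = pd.concat(
        [
            pd.DataFrame(
                {
                    "stage": "TwoStep",
                    "op": "outlier",
                    "sample_id": outlier_log["sample_id"],
                    "breed": outlier_log["breed"],
                    "detail": [
                        f"iter {i}, distance {d:.2f} > {c:.2f}"
                        for i, d, c in zip(
                            outlier_log["iteration"],
                            outlier_log["distance"],
                            outlier_log["cutoff"],
                        )
                    ],
                }
            ),
            pd.DataFrame(
                {
                    "stage": "TwoStep",
                    "op": "prune_related",
                    "sample_id": prune_log["removed_id"],
                    "breed": prune_log["breed"],
                    "detail": [
                        f"UAR {v:.3f} with {p}"
                        for v, p in zip(
                            prune_log["uar_value"], prune_log["partner_id"]
                        )
                    ],
                }
            ),
        ],
        ignore_index=True,
    )
    return DatasetStage("TwoStep", after_outliers.subset_samples(retained), prov)


def stage_tables(
    stage: DatasetStage,
    rarefy_to: int | None = None,
    pool_size: int = 1000,
    seed: int = 0,
    block_kwargs: dict | None = None,
) -> dict:
    """All per-stage analyses: diversity table, distance matrices,
    allelic partition, contributions and pool solution."""
    builder = blocks_builder(**(block_kwargs or {}))
    blk = builder(stage.dataset)
    out: dict = {"stage": stage.label}
    out["diversity"] = diversity.diversity_table(blk, rarefy_to=rarefy_to)
    for metric in ("GST", "DEST", "NeiDA"):
        out[metric] = differentiation.distance_matrix(blk, metric=metric)
    part = metapop.allelic_partition(blk)
    out["partition"] = part.as_dict()
    if len(blk.breed_names()) >= 3:
        out["contributions"] = metapop.breed_contributions(blk)
    pool = metapop.optimize_pool(blk, pool_size=pool_size, seed=seed)
    out["pool"] = pd.DataFrame(
        {"count": pool.counts, "percent": pool.percentages()}
    )
    out["pool_expected_alleles"] = pool.expected_alleles
    return out


def run_full_analysis(
    dataset: GenotypeDataset,
    out_dir: str | Path,
    uar_threshold: float = 0.25,
    alpha: float = outliers.ALPHA_DEFAULT,
    min_breed_n: int = 14,
    pool_size: int = 1000,
    seed: int = 0,
    rarefy_to: int | None = None,
    pca_components: int = 4,
) -> dict:
    """Run Init, OneStep and TwoStep stages and write the report bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    init = DatasetStage("Init", dataset.copy())
    ones = one_step(dataset, uar_threshold=uar_threshold)
    twos = two_step(
        dataset,
        uar_threshold=uar_threshold,
        alpha=alpha,
        min_breed_n=min_breed_n,
        seed=seed,
    )
    results: dict = {"seed": seed}
    header = f"# seed={seed}\n"
    for stage in (init, ones, twos):
        tabs = stage_tables(
            stage, rarefy_to=rarefy_to, pool_size=pool_size, seed=seed
        )
        results[stage.label] = tabs
        prefix = out_dir / stage.label
        _write_tsv(tabs["diversity"], prefix.with_name(f"{stage.label}_diversity.tsv"), header)
        for metric in ("GST", "DEST", "NeiDA"):
            _write_tsv(
                tabs[metric], prefix.with_name(f"{stage.label}_{metric}.tsv"), header
            )
            differentiation.export_distances(
                tabs[metric], prefix.with_name(f"{stage.label}_{metric}")
            )
        if "contributions" in tabs:
            _write_tsv(
                tabs["contributions"],
                prefix.with_name(f"{stage.label}_contributions.tsv"),
                header,
            )
        _write_tsv(tabs["pool"], prefix.with_name(f"{stage.label}_pool.tsv"), header)
        stage.provenance.to_csv(
            prefix.with_name(f"{stage.label}_provenance.tsv"), sep="\t", index=False
        )
    # stage-difference table for the differentiation shift
    diff = results["TwoStep"]["DEST"] - results["OneStep"]["DEST"].reindex(
        index=results["TwoStep"]["DEST"].index,
        columns=results["TwoStep"]["DEST"].columns,
    )
    results["DEST_shift"] = diff
    _write_tsv(diff, out_dir / "DEST_TwoStep_minus_OneStep.tsv", header)
    pca, eig = differentiation.pca_scores(dataset, n_components=pca_components)
    with open(out_dir / "pca_scores.tsv", "w") as fh:
        fh.write("# eigenvalues: " + " ".join(f"{v:.6g}" for v in eig) + "\n")
        pca.to_csv(fh, sep="\t", index=False)
    return results


def _write_tsv(df: pd.DataFrame, path: Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", float_format="%.10g")
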