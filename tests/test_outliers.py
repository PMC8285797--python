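"""Admixture-signature features and robust outlier detection."""

import warnings

import numpy as np
import pandas as pd
import pytest

from blockdiv import outliers, pipeline, relatedness, simdata

from conftest import small_config, single_block_dataset


@pytest.fixture(scope="module")
def admixed_panel():
    """3 breeds x 20, two animals of B01 admixed at alpha=0.5 from B02."""
    cfg = small_config(
        seed=71,
        n_snps=4000,
        admixture_events=[simdata.AdmixtureEvent("B01", "B02", 0.5, 2)],
    )
    ds, truth = simdata.simulate(cfg)
    uar = relatedness.compute_uar(ds)
    blk = pipeline._blocks_builder()(ds)
    return ds, truth, uar, blk


class TestFeatures:
    def test_admixed_animals_shift_in_expected_directions(self, admixed_panel):
        ds, truth, uar, blk = admixed_panel
        feat = outliers.compute_outlier_features(ds, uar, blk, "B01", standardize=False)
        admixed = truth.table[truth.table["label"] == "admixed"]["sample_id"]
        pure = [s for s in feat.index if s not in set(admixed)]
        assert feat.loc[admixed, "f1"].max() < feat.loc[pure, "f1"].min()
        assert feat.loc[admixed, "f2"].min() > np.median(feat.loc[pure, "f2"])
        assert feat.loc[admixed, "f3"].min() > np.median(feat.loc[pure, "f3"])

    def test_foreign_allele_proportion_bounds(self, admixed_panel):
        ds, truth, uar, blk = admixed_panel
        for breed in ("B01", "B02"):
            feat = outliers.compute_outlier_features(
                ds, uar, blk, breed, standardize=False
            )
            assert ((feat["f3"] >= 0) & (feat["f3"] <= 1)).all()
            assert (feat["f4"] >= 0).all()

    def test_fully_private_animal_has_f3_one(self):
        """An animal whose every block allele is absent from its own breed
        but present in another breed scores f3 = 1."""
        blk = single_block_dataset(
            {
                "X": [("0000", "0001"), ("0000", "0000"), ("0000", "0001"),
                      ("1111", "1110")],
                "Y": [("1111", "1110"), ("1111", "1110"), ("1111", "1111")],
            }
        )
        f3 = outliers._foreign_allele_proportion(blk, "X")
        assert f3[3] == 1.0  # the stray animal carries only Y alleles
        assert (f3[:3] == 0.0).all()

    def test_zero_mad_column_dropped_with_warning(self):
        feat = pd.DataFrame({"f1": [1.0, 2, 3, 4, 5], "f4": [0.0] * 5})
        with pytest.warns(UserWarning, match="zero MAD"):
            out = outliers.robust_standardize(feat)
        assert list(out.columns) == ["f1"]

    def test_unknown_breed_rejected(self, admixed_panel):
        ds, truth, uar, blk = admixed_panel
        with pytest.raises(ValueError, match="missing"):
            outliers.compute_outlier_features(ds, uar, blk, "missing")


class TestDetect:
    def test_insufficient_sample_is_error(self):
        feat = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(ValueError, match="insufficient sample"):
            outliers.detect_outliers(feat)

    def test_gross_outlier_always_flagged(self):
        for seed in range(10):
            rng = np.random.default_rng(3000 + seed)
            x = rng.standard_normal((30, 4))
            x[0] = 10.0  # ten robust SDs out in every coordinate
            res = outliers.detect_outliers(pd.DataFrame(x), random_state=seed)
            assert res.table["flagged"].iloc[0]
            assert res.table["distance"].iloc[0] == res.table["distance"].max()

    def test_flag_iff_distance_above_cutoff(self):
        rng = np.random.default_rng(1)
        res = outliers.detect_outliers(pd.DataFrame(rng.standard_normal((50, 3))))
        t = res.table
        assert ((t["distance"] > t["cutoff"]) == t["flagged"]).all()

    def test_singular_scatter_falls_back_to_univariate(self):
        x = np.zeros((20, 3))
        x[:, 0] = np.linspace(-1, 1, 20)
        x[0, 0] = 50.0
        x[:, 1] = x[:, 0] * 2.0  # exactly collinear
        x[:, 2] = x[:, 0] - 1.0
        with pytest.warns(UserWarning, match="singular"):
            res = outliers.detect_outliers(pd.DataFrame(x))
        assert res.fallback
        assert res.table["flagged"].iloc[0]

    def test_maxnull_is_family_wise_conservative(self):
        """On clean Gaussian breeds the max-null rule flags anything in
        roughly alpha of the datasets, not alpha of the animals."""
        flags = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(7000 + seed)
            x = pd.DataFrame(rng.standard_normal((30, 3)))
            res = outliers.detect_outliers(x, cutoff_method="maxnull", random_state=seed)
            flags += res.table["flagged"].any()
        assert flags <= 8  # ~2.5% expected; allow generous Monte-Carlo slack


class TestIterate:
    def test_recovers_injected_admixture_small_panel(self):
        hits, fps = [], []
        for seed in range(3):
            cfg = small_config(
                seed=81 + seed,
                n_snps=4000,
                admixture_events=[
                    simdata.AdmixtureEvent("B01", "B02", 0.5, 2),
                    simdata.AdmixtureEvent("B03", "B01", 0.5, 2),
                ],
            )
            ds, truth = simdata.simulate(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                retained, log = outliers.iterate_outlier_removal(
                    ds, pipeline._blocks_builder(), seed=seed
                )
            removed = set(ds.sample_ids) - set(retained)
            admixed = set(truth.labels_of("admixed"))
            hits.append(len(removed & admixed) / len(admixed))
            fps.append(len(removed - admixed))
        assert np.mean(hits) >= 0.9
        assert sum(fps) <= 6

    def test_min_breed_guard_blocks_removal(self):
        """A breed at the inclusion minimum keeps its animals even when
        flagged; the guard freezes the breed with a warning."""
        cfg = small_config(
            seed=91,
            n_per_breed=14,
            n_snps=3000,
            admixture_events=[simdata.AdmixtureEvent("B01", "B02", 1.0, 1)],
        )
        ds, truth = simdata.simulate(cfg)
        with pytest.warns(UserWarning, match="inclusion minimum"):
            retained, log = outliers.iterate_outlier_removal(
                ds, pipeline._blocks_builder(), min_breed_n=14, seed=0
            )
        assert len(retained) == ds.n_samples
        assert len(log) == 0

    def test_monotone_distance_in_admixture_proportion(self):
        """Mean robust distance of injected animals increases with alpha."""
        means = []
        for alpha in (0.1, 0.25, 0.5):
            dists = []
            for seed in range(3):
                cfg = small_config(
                    seed=95 + seed,
                    n_snps=3000,
                    admixture_events=[simdata.AdmixtureEvent("B01", "B02", alpha, 2)],
                )
                ds, truth = simdata.simulate(cfg)
                uar = relatedness.compute_uar(ds)
                blk = pipeline._blocks_builder()(ds)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    feat = outliers.compute_outlier_features(ds, uar, blk, "B01")
                    res = outliers.detect_outliers(feat, random_state=seed)
                admixed = truth.table[truth.table["label"] == "admixed"]["sample_id"]
                dists.append(res.table.loc[admixed, "distance"].mean())
            means.append(np.mean(dists))
        assert means[0] < means[1] < means[2]

    def test_retained_set_order_independent(self):
        cfg = small_config(
            seed=97,
            n_snps=3000,
            admixture_events=[simdata.AdmixtureEvent("B02", "B03", 0.5, 2)],
        )
        ds, _ = simdata.simulate(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            retained1, _ = outliers.iterate_outlier_removal(
                ds, pipeline._blocks_builder(), seed=5
            )
            perm = list(np.random.default_rng(3).permutation(ds.sample_ids))
            retained2, _ = outliers.iterate_outlier_removal(
                _reorder(ds, perm), pipeline._blocks_builder(), seed=5
            )
        assert sorted(retained1) == sorted(retained2)


def _reorder(ds, new_order):
    import numpy as np

    idx = [ds.sample_ids.index(s) for s in new_order]
    rows = np.empty(2 * len(idx), dtype=int)
    rows[0::2] = np.asarray(idx) * 2
    rows[1::2] = np.asarray(idx) * 2 + 1
    from dataclasses import replace

    return replace(
        ds,
        sample_ids=[ds.sample_ids[i] for i in idx],
        breeds=ds.breeds[idx].copy(),
        haplotypes=ds.haplotypes[rows].copy(),
    )
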