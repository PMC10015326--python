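import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairedg.morphometrics import (
    DEFAULT_PAIRS,
    centroid_size,
    ild_name,
    interlandmark_distances,
    mahalanobis_filter,
    paired_sire_filter,
    procrustes_align,
    read_tps,
    scale_traits,
    unscale_traits,
    wing_traits,
    write_tps,
)
from pairedg.pedigree import Pedigree


def random_wing(rng, scale=1.0):
    base = np.array(
        [[0, 0], [2, 0.5], [3.5, 1.2], [4, 2.5], [3, 3.5], [1.8, 3.2], [0.8, 2.5], [0.3, 1.5], [1.5, 1.8]],
        dtype=float,
    )
    return scale * (base + 0.05 * rng.normal(size=base.shape))


class TestCentroidSize:
    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert centroid_size(square) == pytest.approx(np.sqrt(2))

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        config = random_wing(rng)
        assert centroid_size(3.7 * config) == pytest.approx(3.7 * centroid_size(config))

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        config = random_wing(rng)
        assert centroid_size(config + [5.0, -2.0]) == pytest.approx(centroid_size(config))

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        config = random_wing(rng)
        centroid = config.mean(axis=0)
        brute = np.sqrt(sum((x - centroid[0]) ** 2 + (y - centroid[1]) ** 2 for x, y in config))
        assert centroid_size(config) == pytest.approx(brute)

    def test_coincident_error(self):
        with pytest.raises(ValueError, match="coincident"):
            centroid_size(np.ones((9, 2)))


def rotation(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestProcrustes:
    def test_exact_superimposition(self):
        rng = np.random.default_rng(3)
        config = random_wing(rng)
        moved = 2.5 * config @ rotation(0.7).T + [4.0, -1.0]
        aligned, cs = procrustes_align(np.stack([config, moved]))
        assert np.allclose(aligned[0], aligned[1], atol=1e-8)
        assert cs[1] == pytest.approx(2.5 * cs[0])

    def test_normalization_contract(self):
        rng = np.random.default_rng(4)
        configs = np.stack([random_wing(rng) for _ in range(12)])
        aligned, _ = procrustes_align(configs)
        for a in aligned:
            assert np.allclose(a.mean(axis=0), 0.0, atol=1e-10)
            assert np.sqrt((a**2).sum()) == pytest.approx(1.0)

    def test_beats_centering_only(self):
        rng = np.random.default_rng(5)
        base = random_wing(rng)
        configs = np.stack(
            [base @ rotation(rng.uniform(-0.8, 0.8)).T + 0.02 * rng.normal(size=base.shape)
             for _ in range(15)]
        )
        aligned, _ = procrustes_align(configs)

        def sumsq(x):
            return ((x - x.mean(axis=0)) ** 2).sum()

        centred = configs - configs.mean(axis=1, keepdims=True)
        centred /= np.sqrt((centred**2).sum(axis=(1, 2)))[:, None, None]
        assert sumsq(aligned) < sumsq(centred)

    def test_rotations_are_proper(self):
        """Reflected copies are not mirror-matched (determinant +1 rotations only)."""
        rng = np.random.default_rng(6)
        config = random_wing(rng)
        reflected = config @ np.diag([-1.0, 1.0])
        aligned, _ = procrustes_align(np.stack([config, reflected]))
        assert not np.allclose(aligned[0], aligned[1], atol=1e-3)

    def test_needs_two(self):
        with pytest.raises(ValueError):
            procrustes_align(random_wing(np.random.default_rng(0))[None])


class TestInterlandmarkDistances:
    def test_coincident_pair_zero(self):
        config = np.zeros((9, 2))
        config[4] = [1.0, 1.0]  # landmarks 1 and 2 coincide at origin
        out = interlandmark_distances(config, [(1, 2)])
        assert out[0] == 0.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        config = random_wing(rng)
        rotated = config @ rotation(1.1).T
        d1 = interlandmark_distances(config, DEFAULT_PAIRS)
        d2 = interlandmark_distances(rotated, DEFAULT_PAIRS)
        assert np.allclose(d1, d2)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            config = random_wing(rng)
            ab, bc, ac = interlandmark_distances(config, [(1, 5), (5, 9), (1, 9)])
            assert ac <= ab + bc + 1e-12

    def test_pair_index_error(self):
        with pytest.raises(ValueError, match="outside"):
            interlandmark_distances(np.zeros((9, 2)), [(0, 5)])

    def test_unit_cs_distances(self):
        """ILDs computed on aligned coordinates are 'in units of CS'."""
        rng = np.random.default_rng(9)
        configs = np.stack([random_wing(rng), 10 * random_wing(rng)])
        aligned, _ = procrustes_align(configs)
        d_small, d_big = interlandmark_distances(aligned, DEFAULT_PAIRS)
        assert d_small == pytest.approx(d_big, rel=0.2)  # scale removed


class TestScaling:
    def make_table(self):
        return pd.DataFrame({"CS": [1.1, 2.0], "ILD1.5": [0.25, 0.3], "ILD2.8": [0.4, 0.1]})

    def test_constants(self):
        out = scale_traits(self.make_table())
        assert out["ILD1.5"].iloc[0] == pytest.approx(250.0)
        assert out["CS"].iloc[0] == pytest.approx(220.0)
        assert out.attrs["scaling"] == {"ild": 1000.0, "cs": 200.0}

    def test_round_trip(self):
        table = self.make_table()
        back = unscale_traits(scale_traits(table))
        pd.testing.assert_frame_equal(back, table)


class TestMahalanobisFilter:
    def null_table(self, n, t=11, seed=0):
        rng = np.random.default_rng(seed)
        cov = 0.5 * np.eye(t) + 0.5
        data = rng.multivariate_normal(np.zeros(t), cov, size=n)
        df = pd.DataFrame(data, columns=[f"z{k}" for k in range(t)])
        df["observer"] = rng.choice(["a", "b", "c"], size=n)
        df["generation"] = rng.choice([1, 2], size=n)
        return df

    def test_null_removal_fraction_matches_alpha(self):
        df = self.null_table(100_000)
        traits = [c for c in df.columns if c.startswith("z")]
        kept, removed, _ = mahalanobis_filter(df, traits, alpha=0.001, df=11)
        frac = len(removed) / len(df)
        # chi2 tail oracle: expect ~0.1%, binomial 4-sigma band
        se = np.sqrt(0.001 * 0.999 / len(df))
        assert abs(frac - 0.001) < 4 * se + 2e-4

    def test_injected_outlier_removed(self):
        df = self.null_table(2000, seed=1)
        traits = [c for c in df.columns if c.startswith("z")]
        df.loc[0, traits] = 10.0 * df[traits].std().to_numpy() * np.sign(
            np.random.default_rng(0).normal(size=11)
        )
        kept, removed, d2 = mahalanobis_filter(df, traits, alpha=0.001, df=11)
        assert 0 in removed.index
        crit = stats.chi2.ppf(1 - 0.001, 11)
        assert d2[0] > crit

    def test_alpha_one_removes_everything(self):
        df = self.null_table(200, seed=2)
        traits = [c for c in df.columns if c.startswith("z")]
        kept, removed, _ = mahalanobis_filter(df, traits, alpha=1.0 - 1e-12, df=11)
        assert len(kept) == 0

    def test_alpha_to_zero_removes_nothing(self):
        df = self.null_table(200, seed=3)
        traits = [c for c in df.columns if c.startswith("z")]
        kept, removed, _ = mahalanobis_filter(df, traits, alpha=1e-300, df=11)
        assert len(removed) == 0

    def test_singular_covariance_names_traits(self):
        df = self.null_table(500, t=3, seed=4)
        df["z3"] = df["z0"] + df["z1"]  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            mahalanobis_filter(df, ["z0", "z1", "z2", "z3"])

    def test_centring_respects_strata(self):
        """A large stratum-level shift must not trigger removals."""
        df = self.null_table(5000, t=3, seed=5)
        df.loc[df["observer"] == "a", ["z0", "z1", "z2"]] += 50.0
        traits = ["z0", "z1", "z2"]
        kept, removed, _ = mahalanobis_filter(df, traits, alpha=0.001, df=3)
        assert len(removed) < 0.01 * len(df)


class TestOutlierRecovery:
    def test_filter_recovers_injected_outliers_on_11_traits(self):
        """End-to-end: >=90% of 1% injected 10-SD contaminants are caught."""
        from pairedg.synthetic_data import (
            DesignParams, FixedEffectSpec, LocusSet, inject_outliers, simulate_dataset,
        )

        t = 11
        loci = LocusSet.additive(30, t, q=0.5, a=0.5, seed=20, loading_scale=0.15)
        params = DesignParams(n_pairs=60, n_generations=2, n_traits=t, seed=21)
        ped, _, phen = simulate_dataset(
            params, loci, 0.02 * np.eye(t), 0.5 * np.eye(t),
            FixedEffectSpec(trait_means=tuple([10.0] * t)),
            outlier_fraction=0.0,
        )
        traits = [c for c in phen.columns if c.startswith("trait")]
        dirty = inject_outliers(phen, 0.01, 10.0, seed=22, trait_names=traits)
        kept, removed, _ = mahalanobis_filter(dirty, traits, alpha=0.001, df=t)
        truth = dirty["is_outlier"]
        recovered = removed["is_outlier"].sum() / truth.sum()
        assert truth.sum() > 0
        assert recovered >= 0.90
        # false-positive rate stays near the nominal alpha
        assert (~removed["is_outlier"]).sum() <= max(3, 0.01 * len(dirty))


class TestPairedSireFilter:
    def make_population(self):
        rows = [
            {"id": "s1", "sire": None, "dam": None},
            {"id": "s2", "sire": None, "dam": None},
            {"id": "d1", "sire": None, "dam": None},
            {"id": "d2", "sire": None, "dam": None},
        ]
        recs = []
        for sire, arms in [("s1", ["outbred", "inbred"]), ("s2", ["outbred", "outbred"])]:
            for k, arm in enumerate(arms):
                i = f"{sire}o{k}"
                rows.append({"id": i, "sire": sire, "dam": "d1"})
                recs.append({"id": i, "arm": arm, "y": 1.0})
        ped = Pedigree.from_records(rows).validate()
        return pd.DataFrame(recs), ped

    def test_single_arm_sire_dropped(self):
        table, ped = self.make_population()
        out = paired_sire_filter(table, ped)
        assert set(out["id"]) == {"s1o0", "s1o1"}

    def test_one_plus_one_retained(self):
        table, ped = self.make_population()
        out = paired_sire_filter(table, ped)
        sire_arms = out.groupby(out["id"].str[:2])["arm"].agg(set)
        assert sire_arms["s1"] == {"outbred", "inbred"}

    def test_brute_force_tally_on_synthetic_population(self):
        from pairedg.synthetic_data import DesignParams, simulate_mcn_pedigree

        ped = simulate_mcn_pedigree(DesignParams(n_pairs=30, n_generations=2, seed=13))
        meas = ped.df[ped.df["arm"].isin(["outbred", "inbred"])].copy()
        table = meas[["id", "sire", "arm"]].copy()
        # knock out the inbred arm for ~10% of sires
        rng = np.random.default_rng(0)
        sires = table["sire"].unique()
        knockout = set(rng.choice(sires, size=len(sires) // 10, replace=False))
        table = table[~((table["sire"].isin(knockout)) & (table["arm"] == "inbred"))]
        out = paired_sire_filter(table, ped)
        # independent group-by oracle
        expected = 0
        for sire, grp in table.groupby("sire"):
            arms = set(grp["arm"])
            if {"outbred", "inbred"} <= arms:
                expected += len(grp)
        assert len(out) == expected
        assert not out["sire"].isin(knockout).any()


class TestTps:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        configs = np.stack([random_wing(rng) for _ in range(3)])
        ids = ["w1", "w2", "w3"]
        path = tmp_path / "wings.tps"
        write_tps(path, configs, ids)
        back, back_ids = read_tps(path)
        assert back_ids == ids
        assert np.allclose(back, configs, atol=1e-6)

    def test_missing_file_content(self, tmp_path):
        path = tmp_path / "empty.tps"
        path.write_text("\n")
        with pytest.raises(ValueError, match="no landmark"):
            read_tps(path)


class TestSyntheticLandmarks:
    def test_round_trip_through_pipeline(self, tmp_path):
        from pairedg.synthetic_data import simulate_landmarks

        configs, ids = simulate_landmarks(30, seed=1)
        assert configs.shape == (30, 9, 2)
        path = tmp_path / "synthetic.tps"
        write_tps(path, configs, ids)
        back, back_ids = read_tps(path)
        assert back_ids == ids
        table = scale_traits(wing_traits(back, pd.DataFrame({"id": back_ids})))
        assert len(table) == 30
        # size variation survives alignment via CS; shape noise stays small
        assert table["CS"].std() > 0

    def test_deterministic_given_seed(self):
        from pairedg.synthetic_data import simulate_landmarks

        a, _ = simulate_landmarks(5, seed=9)
        b, _ = simulate_landmarks(5, seed=9)
        assert np.array_equal(a, b)


class TestWingTraitsPipeline:
    def test_full_construction(self):
        rng = np.random.default_rng(11)
        configs = np.stack([random_wing(rng, scale=rng.uniform(0.8, 1.2)) for _ in range(20)])
        meta = pd.DataFrame({"id": [f"w{k}" for k in range(20)]})
        table = wing_traits(configs, meta)
        assert list(table.columns[:2]) == ["id", "CS"]
        assert len([c for c in table.columns if c.startswith("ILD")]) == 10
        assert (table["CS"] > 0).all()
        assert table[[ild_name(p) for p in DEFAULT_PAIRS]].ge(0).all().all()

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        configs = np.stack([random_wing(rng) for _ in range(5)])
        t1 = wing_traits(configs)
        t2 = wing_traits(configs)
        pd.testing.assert_frame_equal(t1, t2)
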