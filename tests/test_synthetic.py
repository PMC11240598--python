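"""Synthetic cluster shapes, fields, and cohorts."""

import numpy as np
import pytest

from cytocluster import diagnostics as dg
from cytocluster import morphometry as mm
from cytocluster import prep
from cytocluster import prognostics as pg
from cytocluster import synthetic as syn


def _measure(mask):
    return mm.measure_clusters(mask.astype(int))[0]


def _masks_at_amplitude(amp, n, radius=30.0, seed0=2000):
    """n valid cluster masks at a roughness level, skipping rejected
    draws (overly large perturbations raise by design)."""
    out = []
    i = 0
    while len(out) < n:
        try:
            out.append(syn.generate_cluster_mask(syn.ClusterShapeParams(
                radius, roughness_amplitude=amp, seed=seed0 + i),
                canvas=(160, 160)))
        except ValueError:
            pass
        i += 1
    return out


class TestClusterMask:
    def test_smooth_disk_measures_circular(self):
        mask = syn.generate_cluster_mask(syn.ClusterShapeParams(50.0))
        f = _measure(mask)
        assert abs(f.circularity - 1.0) <= 0.03
        assert f.solidity > 0.95

    def test_deterministic_for_fixed_seed(self):
        p = syn.ClusterShapeParams(30.0, roughness_amplitude=0.2, seed=7)
        assert np.array_equal(syn.generate_cluster_mask(p),
                              syn.generate_cluster_mask(p))

    def test_single_connected_component(self, rng):
        for seed in range(10):
            p = syn.ClusterShapeParams(25.0, roughness_amplitude=0.25,
                                       roughness_exponent=1.1, seed=seed)
            try:
                mask = syn.generate_cluster_mask(p)
            except ValueError:
                continue
            assert prep.label_clusters(mask, min_area=1).max() == 1

    def test_excessive_roughness_raises(self):
        with pytest.raises(ValueError, match="roughness"):
            # huge amplitude forces r(theta) <= 0 for some seed
            for seed in range(20):
                syn.generate_cluster_mask(syn.ClusterShapeParams(
                    20.0, roughness_amplitude=2.0, seed=seed))

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            syn.ClusterShapeParams(-1.0)
        with pytest.raises(ValueError):
            syn.ClusterShapeParams(10.0, eccentricity=1.0)
        with pytest.raises(ValueError):
            syn.ClusterShapeParams(10.0, roughness_exponent=0.0)

    def test_roughness_monotonicity(self):
        """Mean circularity strictly decreases and per-cluster box-count
        dimension does not decrease as the boundary gets rougher
        (Monte-Carlo over 50 masks per amplitude, fixed seed set).
        Solidity is compared only between levels with actual
        protrusions (0.1 upward): in the near-smooth limit its true
        concavity deficit (~1e-3) is smaller than the ~1e-2 pixel-
        discretization bias of the corner hull, so the 0 -> 0.1 step
        carries no measurable signal."""
        circ, sol, fd = [], [], []
        for amp in (0.0, 0.1, 0.2, 0.4):
            feats = [_measure(m) for m in _masks_at_amplitude(amp, 50)]
            circ.append(np.mean([f.circularity for f in feats]))
            sol.append(np.mean([f.solidity for f in feats]))
            fd.append(np.mean([mm.boxcount_fd(m)
                               for m in _masks_at_amplitude(amp, 50)]))
        assert all(a > b for a, b in zip(circ, circ[1:]))
        assert all(a >= b for a, b in zip(sol[1:], sol[2:]))
        assert all(b >= a - 1e-12 for a, b in zip(fd, fd[1:]))


class TestField:
    def test_zero_clusters_gives_empty_field(self, rng):
        cfg = syn.default_cohort_config()
        fs = syn.generate_field(cfg, "Normal", rng, n_clusters=0)
        assert not fs.mask.any()
        res = prep.binarize(fs.image)
        lab = prep.label_clusters(res.mask, min_area=64)
        assert lab.max() == 0

    def test_seven_clusters_recovered_by_labeling(self, rng):
        cfg = syn.default_cohort_config()
        fs = syn.generate_field(cfg, "Normal", rng, n_clusters=7)
        assert fs.n_clusters == 7
        # ground truth masks are disjoint
        total = sum(m.sum() for m in fs.cluster_masks)
        assert total == fs.mask.sum()
        # and the full prep path on the noisy image recovers exactly 7
        res = prep.binarize(fs.image, method="isodata")
        lab = prep.label_clusters(res.mask, connectivity=8, min_area=64)
        assert lab.max() == 7

    def test_malignant_fields_have_higher_fd(self, rng):
        """Benign vs malignant shape parameters separate the field-level
        box-count dimension (Monte-Carlo over 100 fields)."""
        cfg = syn.default_cohort_config()
        fd = {"Normal": [], "EM_G2": []}
        for _ in range(50):
            for cls in fd:
                fs = syn.generate_field(cfg, cls, rng)
                if fs.mask.any():
                    fd[cls].append(mm.boxcount_fd(fs.mask))
        assert np.mean(fd["EM_G2"]) > np.mean(fd["Normal"]) + 0.05

    def test_impossible_placement_fails_loudly(self, rng):
        cfg = syn.default_cohort_config(field_size=96)
        with pytest.raises(RuntimeError, match="place"):
            syn.generate_field(cfg, "EM_G3", rng, n_clusters=12)


class TestCohort:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_cohort():
        cfg = syn.default_cohort_config(
            seed=42, counts={"Normal": 12, "EH": 2, "AEH": 2, "EM_G1": 5,
                             "EM_G2": 4, "EM_G3": 3, "Others": 2},
            field_size=256, clusters_per_field_mean=4.0)
        df, _ = syn.generate_cohort(cfg)
        return df

    def test_counts_and_columns(self, small_cohort):
        df = small_cohort
        assert len(df) == 30
        assert df["histology"].value_counts()["Normal"] == 12
        for col in ("age", "cytology", "circularity", "solidity",
                    "fractal_dimension", "cluster_count", "time_months",
                    "event"):
            assert col in df.columns
        assert (df["time_months"] >= 0).all()
        assert df["age"].min() >= 18

    def test_age_means_converge_to_config(self, small_cohort):
        ages = small_cohort.query("histology == 'Normal'")["age"]
        assert abs(ages.mean() - 49.9) < 3 * 12.2 / np.sqrt(len(ages))

    def test_morphology_separates_classes(self, small_cohort):
        df = small_cohort
        benign = df["histology"].isin(["Normal", "EH"])
        assert df.loc[~benign, "fractal_dimension"].mean() > \
            df.loc[benign, "fractal_dimension"].mean()
        assert df.loc[~benign, "circularity"].mean() < \
            df.loc[benign, "circularity"].mean()

    def test_determinism(self):
        cfg = dict(seed=9, counts={"Normal": 3, "EM_G2": 3},
                   field_size=192, clusters_per_field_mean=3.0)
        a, _ = syn.generate_cohort(syn.default_cohort_config(**cfg))
        b, _ = syn.generate_cohort(syn.default_cohort_config(**cfg))
        assert a.equals(b)

    def test_truncated_ages_never_below_floor(self, rng):
        ages = syn._truncated_normal_age(25.0, 15.0, 500, rng)
        assert ages.min() >= 18.0

    def test_config_validation(self):
        cfg = syn.default_cohort_config()
        cfg.cytology_probs["Normal"] = (0.5, 0.2, 0.2)
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()


class TestTabularCohort:
    def test_binormal_design_auc(self, rng):
        """The feature generator hits its designed class separation:
        analytic AUC Phi(shift/sqrt(2)) matches the empirical AUC."""
        shift = syn.binormal_shift(0.85)
        df = syn.sample_feature_cohort(2000, 2000, rng,
                                       {"fractal_dimension": shift})
        x = df["fractal_dimension"].to_numpy()
        lab = df["positive"].to_numpy()
        auc, _ = dg.delong_variance(x[lab], x[~lab])
        assert auc == pytest.approx(0.85, abs=0.02)
        assert syn.binormal_auc(0.0, 1.0, shift, 1.0) == pytest.approx(0.85)

    def test_null_betas_give_nominal_logrank_rate(self):
        """With all survival coefficients zero, a median morphology split
        rejects at about the nominal 5% level (200 replicates)."""
        rej = 0
        reps = 200
        rng = np.random.default_rng(77)
        from scipy.stats import chi2
        for _ in range(reps):
            df = syn.sample_feature_cohort(
                40, 40, rng, {"circularity": 0.0},
                survival_betas={"circularity": 0.0})
            x = df["circularity"].to_numpy()
            grp = x <= np.median(x)
            stat = pg.two_group_logrank_chi2(
                df["time_months"].to_numpy(), df["event"].to_numpy(), grp)
            if chi2.sf(stat, 1) < 0.05:
                rej += 1
        assert 0.02 <= rej / reps <= 0.09

    def test_cox_recovers_designed_hazard_ratio(self):
        """n = 2000, log-hazard -1 per SD of circularity: the fitted HR
        is within 15% of exp(-1)."""
        rng = np.random.default_rng(11)
        df = syn.sample_feature_cohort(
            1000, 1000, rng, {"circularity": 0.0},
            survival_betas={"circularity": -1.0})
        z = df["circularity"].to_numpy()
        z = (z - z.mean()) / z.std()
        fit = pg.cox_fit(z[:, None], df["time_months"].to_numpy(),
                         df["event"].to_numpy(), names=["circularity"])
        assert fit.hazard_ratio["circularity"] == pytest.approx(
            np.exp(-1.0), rel=0.15)
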