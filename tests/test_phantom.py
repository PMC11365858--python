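import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats as sps

from myelotype.cohort import (CohortSpec, GroupSpec, LogNormalQuartiles,
                              TruncNormal, generate_cohort,
                              quartiles_to_lognormal, sprintms_cohort_spec)
from myelotype.phantom import (CSF, GM, WM, CapacityError, PhantomParams,
                               generate_phantom)

S26 = np.ones((3, 3, 3), dtype=bool)


class TestGeneratePhantom:
    @pytest.mark.parametrize("target_ml,core_frac", [(2.0, 0.0), (5.0, 0.25),
                                                     (10.0, 0.15)])
    def test_volume_and_core_fraction_hit_targets(self, target_ml, core_frac):
        ph = generate_phantom(PhantomParams(target_t2_volume_ml=target_ml,
                                            t1_core_fraction=core_frac, seed=3))
        n = ph.truth_t2_mask.n_voxels
        assert abs(n - target_ml * 1000) <= 0.1 * target_ml * 1000
        realized = ph.truth_t1_mask.n_voxels / n
        assert abs(realized - core_frac) <= 0.05

    def test_five_ml_at_isotropic_mm_is_about_5000_voxels(self):
        ph = generate_phantom(PhantomParams(voxel_mm=(1, 1, 1),
                                            target_t2_volume_ml=5.0, seed=1))
        assert 4500 <= ph.truth_t2_mask.n_voxels <= 5500

    def test_zero_target_gives_pure_tissue_phantom(self, lesion_free_phantom):
        assert lesion_free_phantom.truth_t2_mask.n_voxels == 0
        assert lesion_free_phantom.truth_t1_mask.n_voxels == 0

    def test_full_core_fraction_saturates_to_t2_mask(self):
        ph = generate_phantom(PhantomParams(target_t2_volume_ml=3.0,
                                            t1_core_fraction=1.0, seed=2))
        assert np.array_equal(ph.truth_t1_mask.data, ph.truth_t2_mask.data)

    def test_mask_nesting_and_tissue_containment(self, small_phantom):
        t1 = small_phantom.truth_t1_mask.data
        t2 = small_phantom.truth_t2_mask.data
        wm = small_phantom.tissue_labels == WM
        assert not (t1 & ~t2).any()
        assert not (t2 & ~wm).any()

    def test_periventricular_lesion_is_one_component_touching_ventricle(self):
        for seed in (0, 1, 2):
            ph = generate_phantom(PhantomParams(target_t2_volume_ml=4.0, seed=seed))
            _, n = ndimage.label(ph.truth_t2_mask.data, structure=S26)
            assert n == 1
            grown = ndimage.binary_dilation(ph.truth_t2_mask.data, structure=S26)
            assert (grown & (ph.tissue_labels == CSF)).any()

    def test_lesion_expands_posteriorly(self):
        """The cap grows at the occipital-horn (posterior) end."""
        ph = generate_phantom(PhantomParams(target_t2_volume_ml=10.0, seed=4))
        vent_y = np.argwhere(ph.tissue_labels == CSF)[:, 1].mean()
        lesion_y = np.argwhere(ph.truth_t2_mask.data)[:, 1].mean()
        assert lesion_y > vent_y

    def test_geometry_shared_across_grids(self, small_phantom):
        ph = small_phantom
        for g in (ph.flair, ph.truth_t2_mask, ph.truth_t1_mask):
            assert g.shape == ph.t1.shape
            assert g.voxel_mm == ph.t1.voxel_mm
        assert ph.tissue_labels.shape == ph.t1.shape

    def test_seed_reproducibility_is_bit_identical(self, small_params):
        a = generate_phantom(small_params)
        b = generate_phantom(small_params)
        assert np.array_equal(a.t1.data, b.t1.data)
        assert np.array_equal(a.flair.data, b.flair.data)
        assert np.array_equal(a.truth_t2_mask.data, b.truth_t2_mask.data)

    def test_capacity_error_when_target_exceeds_wm(self):
        with pytest.raises(CapacityError):
            generate_phantom(PhantomParams(grid_shape=(48, 60, 48),
                                           target_t2_volume_ml=100.0))

    def test_t1_contrast_ordering_enforced(self):
        with pytest.raises(ValueError):
            PhantomParams(gm_mean=120.0, wm_mean=100.0)


class TestQuartilesToLognormal:
    def test_symmetric_toy_case(self):
        mu, sigma = quartiles_to_lognormal(1.0, 0.5, 2.0)
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert sigma == pytest.approx(1.0276, abs=2e-4)

    @pytest.mark.parametrize("median,q1,q3", [(1.0, 0.5, 2.0), (0.12, 0.07, 0.32),
                                              (11.95, 5.32, 22.71)])
    def test_quantile_round_trip(self, median, q1, q3):
        """The fit matches the median and the quartile ratio exactly; both
        quartiles individually only when they are log-symmetric (the family
        has two parameters)."""
        mu, sigma = quartiles_to_lognormal(median, q1, q3)
        dist = sps.lognorm(s=sigma, scale=np.exp(mu))
        assert dist.ppf(0.5) == pytest.approx(median, rel=1e-9)
        assert dist.ppf(0.75) / dist.ppf(0.25) == pytest.approx(q3 / q1, rel=1e-9)

    def test_log_symmetric_quartiles_match_exactly(self):
        mu, sigma = quartiles_to_lognormal(1.0, 0.5, 2.0)
        dist = sps.lognorm(s=sigma, scale=np.exp(mu))
        assert dist.ppf(0.25) == pytest.approx(0.5, rel=1e-9)
        assert dist.ppf(0.75) == pytest.approx(2.0, rel=1e-9)

    @pytest.mark.parametrize("bad", [(1.0, 1.0, 1.0), (1.0, 2.0, 3.0),
                                     (1.0, -0.5, 2.0), (0.0, 0.5, 2.0)])
    def test_invalid_summaries_rejected(self, bad):
        with pytest.raises(ValueError):
            quartiles_to_lognormal(*bad)


class TestGenerateCohort:
    def test_mcms_t1_median_recovered_at_large_n(self):
        spec = CohortSpec(groups=(GroupSpec(
            "MCMS", 2000, t2_ml=TruncNormal(35.24, 15.51, lower=2.0),
            t1_ml=LogNormalQuartiles(0.12, 0.07, 0.32)),), seed=9)
        df = generate_cohort(spec)
        assert 0.102 <= df["t1_ml"].median() <= 0.138

    def test_marginals_within_15pct_at_n500(self):
        spec = sprintms_cohort_spec(seed=21, n_scale=500 / 25)
        df = generate_cohort(spec)
        tms = df[df.group_truth == "TMS"]
        assert tms["t2_ml"].median() == pytest.approx(11.95, rel=0.15)
        iqr = tms["t2_ml"].quantile(0.75) - tms["t2_ml"].quantile(0.25)
        assert iqr == pytest.approx(22.71 - 5.32, rel=0.15)

    def test_t1_never_exceeds_t2(self):
        df = generate_cohort(sprintms_cohort_spec(seed=3))
        assert (df["t1_ml"] <= df["t2_ml"] + 1e-12).all()
        assert (df["ratio_pct"] <= 100.0 + 1e-9).all()

    def test_deterministic_for_fixed_seed(self):
        a = generate_cohort(sprintms_cohort_spec(seed=5))
        b = generate_cohort(sprintms_cohort_spec(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_quartiles_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("X", 10, t2_ml=LogNormalQuartiles(1.0, 1.0, 1.0),
                      ratio_pct=LogNormalQuartiles(1.0, 0.5, 2.0)).t2_ml.params()

    def test_exactly_one_of_t1_or_ratio(self):
        with pytest.raises(ValueError):
            GroupSpec("X", 10, t2_ml=LogNormalQuartiles(10, 5, 20))

    def test_ks_distance_to_specified_lognormal(self):
        """Generated T1 volumes follow the requested log-normal (n=5000)."""
        mu, sigma = quartiles_to_lognormal(0.12, 0.07, 0.32)
        spec = CohortSpec(groups=(GroupSpec(
            "MCMS", 5000, t2_ml=TruncNormal(1000.0, 1.0, lower=2.0),
            t1_ml=LogNormalQuartiles(0.12, 0.07, 0.32)),), seed=13)
        df = generate_cohort(spec)  # huge t2 so clipping never binds
        stat = sps.kstest(df["t1_ml"], sps.lognorm(s=sigma, scale=np.exp(mu)).cdf).statistic
        assert stat < 0.05
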