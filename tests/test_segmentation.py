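"""Segmentation: SUVpeak sphere rule, 40% thresholding, liver mixture fit."""

import numpy as np
import pytest

from prrt_hemtox.phantom import PhantomSpec, generate_phantom
from prrt_hemtox.segmentation import (
    Histogram,
    build_liver_histogram,
    compile_volume_report,
    compute_suvpeak,
    fit_three_gaussians,
    fit_three_gaussians_em,
    identify_normal_component,
    liver_tumour_volume,
    segment_lesion_40pct,
    sphere_radius_mm,
)
from prrt_hemtox.volumes import SUVVolume


def brute_force_suvpeak(volume, region_mask):
    """Independent oracle: for every candidate center, average the SUV of all
    voxels whose centers lie within the 1 mL sphere radius, by explicit
    distance computation over the whole grid."""
    spacing = np.asarray(volume.spacing)
    r = sphere_radius_mm()
    centers = np.argwhere(region_mask)
    all_idx = np.argwhere(np.ones(volume.shape, bool))
    coords = all_idx * spacing
    flat = volume.data.reshape(-1)
    best = (-np.inf, None)
    for c in centers:
        d2 = np.sum((coords - c * spacing) ** 2, axis=1)
        inside = d2 <= r * r + 1e-9
        mean = flat[inside].mean()
        if mean > best[0]:
            best = (mean, tuple(int(x) for x in c))
    return best


def ellipsoid_volume(shape, spacing, center_mm, semi_mm, inside_suv, outside_suv):
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semi_mm))
    data = np.where(q <= 1.0, inside_suv, outside_suv)
    return SUVVolume(data, spacing, {"lesion": q <= 1.0})


class TestSUVPeak:
    def test_constant_field_returns_the_constant(self, uniform_volume):
        res = compute_suvpeak(uniform_volume, "all")
        assert res.value == pytest.approx(3.0)

    def test_single_hot_voxel_at_4mm_spacing(self):
        """One voxel of SUV 100 in zero background: the 1 mL sphere at 4 mm
        isotropic spacing holds 19 voxel centers (offsets of squared index
        norm 0, 1, 2: 1 + 6 + 12), so SUVpeak = 100/19."""
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 100.0
        vol = SUVVolume(data, (4.0, 4.0, 4.0))
        region = np.zeros_like(data, dtype=bool)
        region[7, 7, 7] = True
        res = compute_suvpeak(vol, region)
        assert res.sphere_voxels == 19
        assert res.value == pytest.approx(100.0 / 19.0)

    def test_matches_brute_force_on_hot_ellipsoid(self):
        vol = ellipsoid_volume((20, 20, 20), (3.0, 3.0, 3.0), (30.0, 30.0, 30.0), (12.0, 9.0, 7.0), 10.0, 0.5)
        rng = np.random.default_rng(0)
        vol.data += rng.normal(0, 0.2, vol.shape).clip(-0.4)
        np.clip(vol.data, 0, None, out=vol.data)
        res = compute_suvpeak(vol, "lesion")
        oracle_val, oracle_center = brute_force_suvpeak(vol, vol.mask("lesion"))
        assert res.center == oracle_center
        assert res.value == pytest.approx(oracle_val, rel=1e-9)

    def test_small_region_is_flagged(self):
        data = np.full((12, 12, 12), 2.0)
        region = np.zeros_like(data, dtype=bool)
        region[6, 6, 6] = True
        res = compute_suvpeak(SUVVolume(data, (2.0, 2.0, 2.0)), region)
        assert res.region_smaller_than_sphere
        assert res.value == pytest.approx(2.0)

    def test_empty_region_raises(self, uniform_volume):
        with pytest.raises(ValueError, match="empty"):
            compute_suvpeak(uniform_volume, np.zeros(uniform_volume.shape, bool))


class TestLesionSegmentation:
    def test_plateau_ellipsoid_recovered_within_one_voxel_shell(self):
        spacing = (2.0, 2.0, 2.0)
        semi = (14.0, 11.0, 9.0)
        vol = ellipsoid_volume((32, 32, 32), spacing, (31.0, 31.0, 31.0), semi, 10.0, 0.5)
        seg = segment_lesion_40pct(vol, "lesion")
        lo = 4 / 3 * np.pi * np.prod([max(a - s, 0) for a, s in zip(semi, spacing)]) / 1000
        hi = 4 / 3 * np.pi * np.prod([a + s for a, s in zip(semi, spacing)]) / 1000
        assert lo <= seg.volume_ml <= hi

    def test_uniform_field_returns_whole_mask(self, uniform_volume):
        seg = segment_lesion_40pct(uniform_volume, "all")
        assert seg.voxel_count == uniform_volume.data.size

    def test_region_seeding_selects_only_its_blob(self):
        data = np.full((30, 30, 30), 0.2)
        a = np.zeros_like(data, bool)
        b = np.zeros_like(data, bool)
        a[4:9, 4:9, 4:9] = True
        b[20:26, 20:26, 20:26] = True
        data[a] = 8.0
        data[b] = 8.0
        vol = SUVVolume(data, (3.0, 3.0, 3.0))
        seg = segment_lesion_40pct(vol, a)
        assert (seg.mask & a).sum() == a.sum()
        assert not (seg.mask & b).any()

    def test_volume_is_voxel_count_times_voxel_volume(self):
        vol = ellipsoid_volume((24, 24, 24), (2.0, 3.0, 4.0), (23.0, 34.0, 46.0), (10.0, 12.0, 14.0), 6.0, 0.3)
        seg = segment_lesion_40pct(vol, "lesion")
        assert seg.volume_ml == pytest.approx(seg.voxel_count * 2 * 3 * 4 / 1000)

    def test_volume_non_increasing_in_threshold(self):
        vol = ellipsoid_volume((24, 24, 24), (3.0, 3.0, 3.0), (34.0, 34.0, 34.0), (12.0, 10.0, 8.0), 10.0, 0.5)
        rng = np.random.default_rng(1)
        vol.data *= 1 + rng.normal(0, 0.1, vol.shape)
        np.clip(vol.data, 0, None, out=vol.data)
        vols = [segment_lesion_40pct(vol, "lesion", threshold_fraction=f).volume_ml for f in (0.3, 0.4, 0.6, 0.8)]
        assert all(v1 >= v2 for v1, v2 in zip(vols, vols[1:]))

    def test_axis_permutation_invariance(self):
        vol = ellipsoid_volume((20, 22, 24), (2.0, 3.0, 4.0), (19.0, 31.0, 46.0), (9.0, 11.0, 13.0), 7.0, 0.4)
        # break plateau ties so the winning sphere center is unique
        rng = np.random.default_rng(3)
        vol.data += rng.uniform(0, 0.05, vol.shape)
        seg = segment_lesion_40pct(vol, "lesion")
        perm = (2, 0, 1)
        vol_p = SUVVolume(
            np.transpose(vol.data, perm),
            tuple(vol.spacing[i] for i in perm),
            {"lesion": np.transpose(vol.mask("lesion"), perm)},
        )
        seg_p = segment_lesion_40pct(vol_p, "lesion")
        assert seg_p.suvpeak == pytest.approx(seg.suvpeak, rel=1e-12)
        assert seg_p.volume_ml == pytest.approx(seg.volume_ml)
        assert seg_p.peak_center == tuple(seg.peak_center[i] for i in perm)


class TestHistogram:
    def test_single_value_lands_in_one_bin(self):
        data = np.full((10, 1, 1), 2.05)
        vol = SUVVolume(data, (2.0, 2.0, 2.0), {"liver": np.ones((10, 1, 1), bool)})
        h = build_liver_histogram(vol)
        nz = np.nonzero(h.counts)[0]
        assert len(nz) == 1
        assert h.counts[nz[0]] == 10
        assert h.edges[nz[0]] <= 2.05 < h.edges[nz[0] + 1]

    def test_counts_conserve_mask_size_and_match_tally(self):
        vol, _ = generate_phantom(PhantomSpec(shape=(32, 32, 32), liver_semiaxes_mm=(28.0, 26.0, 22.0), seed=5))
        h = build_liver_histogram(vol, "liver", bin_width=0.1)
        assert h.counts.sum() == vol.mask("liver").sum()
        # independent tally: floor(v / width) indexing over a python loop
        tally = np.zeros(len(h.counts), dtype=int)
        for v in vol.data[vol.mask("liver")]:
            tally[min(int(v / 0.1), len(tally) - 1)] += 1
        assert np.array_equal(tally, h.counts)

    def test_empty_mask_raises(self, uniform_volume):
        with pytest.raises(ValueError, match="empty"):
            build_liver_histogram(uniform_volume, np.zeros(uniform_volume.shape, bool))


def mixture_histogram(n=50_000, seed=0):
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n, p=[0.1, 0.7, 0.2])
    mus = np.array([1.5, 5.0, 15.0])[comp]
    sds = np.array([0.4, 1.0, 4.0])[comp]
    values = np.clip(rng.normal(mus, sds), 0, None)
    side = int(round(n ** (1 / 3))) + 1
    data = np.zeros(side**3)
    data[: values.size] = values
    mask = np.zeros(side**3, bool)
    mask[: values.size] = True
    vol = SUVVolume(data.reshape(side, side, side), (2.0, 2.0, 2.0), {"liver": mask.reshape(side, side, side)})
    return build_liver_histogram(vol), values


class TestMixtureFit:
    def test_parameter_recovery_from_known_mixture(self):
        h, _ = mixture_histogram(seed=3)
        fit = fit_three_gaussians(h)
        assert fit.converged
        for (w, m, s), (wt, mt, st) in zip(fit.components, [(0.1, 1.5, 0.4), (0.7, 5.0, 1.0), (0.2, 15.0, 4.0)]):
            assert m == pytest.approx(mt, rel=0.05)
            assert abs(w - wt) < 0.05

    def test_single_gaussian_degenerates_gracefully(self):
        """On one-population data the extra components absorb ~no weight; with
        the dominant component selected (the operator-override path), the
        mu+sigma rule tags ~15.9% of the values, the normal upper-tail mass."""
        rng = np.random.default_rng(1)
        values = rng.normal(5, 1, 50_000).clip(0)
        vol = SUVVolume(values.reshape(50, 50, 20), (2.0, 2.0, 2.0), {"liver": np.ones((50, 50, 20), bool)})
        fit = fit_three_gaussians(build_liver_histogram(vol))
        dominant = int(np.argmax(fit.weights))
        # the extra components either absorb little weight or overlap the
        # dominant mean; either way they sit near the generating mean of 5
        assert fit.weights[dominant] > 0.6
        for w, m, s in fit.components:
            if w > 0.05:
                assert abs(m - 5.0) < 1.0
        identify_normal_component(fit, override=dominant)
        ml, mask = liver_tumour_volume(vol, "liver", fit)
        frac = mask.sum() / vol.mask("liver").sum()
        assert 0.10 < frac < 0.25  # near the 15.9% upper-tail mass of a Gaussian

    def test_same_histogram_same_fit(self):
        h, _ = mixture_histogram(seed=4)
        f1 = fit_three_gaussians(h)
        f2 = fit_three_gaussians(h)
        assert f1.components == f2.components

    def test_wls_and_em_routes_agree_on_means(self):
        """Cross-check: the histogram WLS fit and an EM fit on the raw values
        recover the same component means."""
        h, values = mixture_histogram(seed=6)
        wls = fit_three_gaussians(h)
        em = fit_three_gaussians_em(values)
        for m_wls, m_em in zip(wls.means, em.means):
            assert m_wls == pytest.approx(m_em, rel=0.05)

    def test_degenerate_histogram_rejected(self):
        h = Histogram(edges=np.array([0.0, 0.1, 0.2]), counts=np.array([50, 60]), total=110)
        with pytest.raises(ValueError, match="3 non-empty"):
            fit_three_gaussians(h)


class TestNormalComponentAndVolume:
    def test_middle_mean_selected(self):
        h, _ = mixture_histogram(seed=7)
        fit = fit_three_gaussians(h)
        idx = identify_normal_component(fit)
        assert fit.means[idx] == pytest.approx(5.0, rel=0.05)

    def test_override_wins(self):
        h, _ = mixture_histogram(seed=7)
        fit = fit_three_gaussians(h)
        assert identify_normal_component(fit, override=0) == 0
        with pytest.raises(ValueError, match="out of range"):
            identify_normal_component(fit, override=5)

    def test_equal_means_tie_breaks_toward_larger_weight(self):
        from prrt_hemtox.segmentation import MixtureFit

        fit = MixtureFit(components=[(0.2, 5.0, 1.0), (0.5, 5.0, 2.0), (0.3, 9.0, 1.0)], converged=True, gof=0.0)
        idx = identify_normal_component(fit)
        assert idx == 1  # among the tied means 5.0, the weight-0.5 component ranks first

    def test_threshold_strictness_and_monotonicity(self):
        vol, _ = generate_phantom(PhantomSpec(seed=8))
        fit = fit_three_gaussians(build_liver_histogram(vol))
        identify_normal_component(fit)
        ml1, m1 = liver_tumour_volume(vol, "liver", fit)
        _, mu, sd = fit.components[fit.normal_index]
        # exact definition: strictly above mu + sd, inside the liver mask
        expect = vol.mask("liver") & (vol.data > mu + sd)
        assert np.array_equal(m1, expect)
        # raising the threshold never increases the volume
        ml2 = (vol.mask("liver") & (vol.data > mu + 2 * sd)).sum() * vol.voxel_volume_ml
        assert ml2 <= ml1

    def test_all_below_threshold_gives_zero(self, uniform_volume):
        from prrt_hemtox.segmentation import MixtureFit

        fit = MixtureFit(components=[(0.2, 1.0, 0.5), (0.6, 5.0, 1.0), (0.2, 9.0, 1.0)], converged=True, gof=0.0)
        fit.normal_index = 1
        ml, mask = liver_tumour_volume(uniform_volume, "all", fit)  # all voxels 3.0 <= 6.0
        assert ml == 0.0 and not mask.any()


class TestVolumeReport:
    def test_compartment_sums(self):
        """Per-compartment medians 11.8 (bone), 42.4 (soft tissue) and 580.5
        (liver) mL add to 634.7 mL."""
        report = compile_volume_report(580.5, [_seg(11.8, "b"), _seg(42.4, "s")], ["bone", "soft_tissue"])
        assert report.total_ml == pytest.approx(634.7)
        assert report.bone_ml == pytest.approx(11.8)

    def test_empty_report(self):
        assert compile_volume_report(0.0).total_ml == 0.0

    def test_order_invariance(self):
        segs = [_seg(3.0, "a"), _seg(5.0, "b"), _seg(7.0, "c")]
        labels = ["bone", "soft_tissue", "bone"]
        r1 = compile_volume_report(10.0, segs, labels)
        r2 = compile_volume_report(10.0, segs[::-1], labels[::-1])
        assert (r1.bone_ml, r1.soft_tissue_ml, r1.total_ml) == (r2.bone_ml, r2.soft_tissue_ml, r2.total_ml)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown compartment"):
            compile_volume_report(1.0, [_seg(1.0, "x")], ["brain"])


def _seg(volume_ml, lesion_id):
    from prrt_hemtox.segmentation import LesionSegment

    return LesionSegment(
        lesion_id=lesion_id, suvpeak=10.0, peak_center=(0, 0, 0), threshold=4.0,
        mask=np.zeros((1, 1, 1), bool), volume_ml=volume_ml, threshold_fraction=0.4,
        connectivity=26, region_smaller_than_sphere=False,
    )
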