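"""PET tumour-volume segmentation.

Two procedures are implemented:

* **Lesion-wise 40%-SUVpeak thresholding** for bone and soft-tissue lesions.
  SUVpeak is the highest mean SUV over placements of a 1 mL sphere (radius
  ~6.2 mm) centered on voxel centers inside the lesion region; the lesion is
  the 26-connected component of voxels at or above 0.40 x SUVpeak that
  contains the peak center.

* **Three-Gaussian liver-histogram method** for liver tumour volume.  All
  liver-mask SUVs are binned (default 0.1 SUV fixed width) and the sum of
  three scaled Gaussians is fitted to the counts by weighted least squares;
  the components represent blood pool, normal parenchyma and tumour.  Every
  liver voxel strictly above the normal-parenchyma mean plus one SD is
  counted as tumour.

Conventions: 0-based voxel indices, physical position = index x spacing
(mm), volumes in mL = mm^3 / 1000.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .volumes import SUVVolume

__all__ = [
    "SPHERE_VOLUME_MM3",
    "sphere_radius_mm",
    "sphere_offsets",
    "SUVPeakResult",
    "compute_suvpeak",
    "LesionSegment",
    "segment_lesion_40pct",
    "Histogram",
    "build_liver_histogram",
    "MixtureFit",
    "fit_three_gaussians",
    "fit_three_gaussians_em",
    "identify_normal_component",
    "liver_tumour_volume",
    "VolumeReport",
    "compile_volume_report",
]

logger = logging.getLogger(__name__)

SPHERE_VOLUME_MM3 = 1000.0


def sphere_radius_mm(volume_mm3: float = SPHERE_VOLUME_MM3) -> float:
    """Radius of the SUVpeak sphere: (3 V / 4 pi)^(1/3), ~6.2 mm for 1 mL."""
    return float((3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def sphere_offsets(spacing: tuple[float, float, float], radius_mm: float | None = None) -> np.ndarray:
    """Integer voxel offsets whose centers lie within ``radius_mm`` of the origin."""
    r = sphere_radius_mm() if radius_mm is None else radius_mm
    spacing = np.asarray(spacing, dtype=float)
    half = np.floor(r / spacing).astype(int)
    axes = [np.arange(-h, h + 1) for h in half]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dist2 = np.sum((grid * spacing) ** 2, axis=1)
    return grid[dist2 <= r * r + 1e-9]


def _region_indices(volume: SUVVolume, region) -> np.ndarray:
    """Normalize a region (mask name, boolean mask or (N,3) indices) to sorted indices."""
    if isinstance(region, str):
        region = volume.mask(region)
    region = np.asarray(region)
    if region.dtype == bool:
        if region.shape != volume.shape:
            raise ValueError(f"region mask shape {region.shape} does not match grid {volume.shape}")
        idx = np.argwhere(region)  # row-major -> lexicographically sorted
    else:
        idx = np.asarray(region, dtype=np.intp).reshape(-1, 3)
        idx = idx[np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))]
        if np.any(idx < 0) or np.any(idx >= np.asarray(volume.shape)):
            raise ValueError("region indices fall outside the grid")
    if idx.size == 0:
        raise ValueError("lesion region is empty")
    return idx


@dataclass
class SUVPeakResult:
    """SUVpeak value, the winning sphere center, and bookkeeping flags."""

    value: float
    center: tuple[int, int, int]
    sphere_voxels: int
    region_smaller_than_sphere: bool


def compute_suvpeak(volume: SUVVolume, region, radius_mm: float | None = None, chunk: int = 4096) -> SUVPeakResult:
    """SUVpeak: highest 1 mL-sphere mean SUV over candidate centers in the region.

    Candidate centers are the voxel centers of the region; a voxel belongs
    to a sphere iff its center lies within the sphere radius of the
    candidate center (voxels outside the grid are excluded from the mean).
    Ties break toward the lexicographically smallest center.  Regions
    smaller than one sphere are still evaluated (the sphere then extends
    beyond the region) and flagged.
    """
    idx = _region_indices(volume, region)
    offs = sphere_offsets(volume.spacing, radius_mm)
    shape = np.asarray(volume.shape)
    data = volume.data
    best_val = -np.inf
    best_center: tuple[int, int, int] | None = None
    for start in range(0, len(idx), chunk):
        cand = idx[start : start + chunk]
        pos = cand[:, None, :] + offs[None, :, :]  # (M, K, 3)
        valid = np.all((pos >= 0) & (pos < shape), axis=2)
        pc = np.clip(pos, 0, shape - 1)
        vals = data[pc[..., 0], pc[..., 1], pc[..., 2]]
        vals = np.where(valid, vals, 0.0)
        means = vals.sum(axis=1) / valid.sum(axis=1)
        j = int(np.argmax(means))  # first occurrence = lexicographically smallest
        if means[j] > best_val:
            best_val = float(means[j])
            best_center = tuple(int(x) for x in cand[j])
    assert best_center is not None
    return SUVPeakResult(
        value=best_val,
        center=best_center,
        sphere_voxels=len(offs),
        region_smaller_than_sphere=len(idx) < len(offs),
    )


@dataclass
class LesionSegment:
    """One segmented lesion: threshold, member voxels and volume."""

    lesion_id: str
    suvpeak: float
    peak_center: tuple[int, int, int]
    threshold: float
    mask: np.ndarray
    volume_ml: float
    threshold_fraction: float
    connectivity: int
    region_smaller_than_sphere: bool

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def segment_lesion_40pct(
    volume: SUVVolume,
    region,
    threshold_fraction: float = 0.40,
    connectivity: int = 26,
    lesion_id: str = "lesion",
) -> LesionSegment:
    """Segment one lesion at ``threshold_fraction`` x SUVpeak.

    The member set is the connected component (26-neighbour by default) of
    ``{SUV >= threshold}`` containing the peak sphere center; volume is
    voxel count x voxel volume.
    """
    peak = compute_suvpeak(volume, region)
    threshold = threshold_fraction * peak.value
    above = volume.data >= threshold
    if not above[peak.center]:
        raise ValueError(f"{lesion_id}: peak center below its own threshold; degenerate lesion")
    labels, _ = ndimage.label(above, structure=_structure(connectivity))
    mask = labels == labels[peak.center]
    return LesionSegment(
        lesion_id=lesion_id,
        suvpeak=peak.value,
        peak_center=peak.center,
        threshold=threshold,
        mask=mask,
        volume_ml=float(mask.sum()) * volume.voxel_volume_ml,
        threshold_fraction=threshold_fraction,
        connectivity=connectivity,
        region_smaller_than_sphere=peak.region_smaller_than_sphere,
    )


# ---------------------------------------------------------------------------
# liver histogram method


@dataclass
class Histogram:
    """Fixed-width SUV histogram of the liver mask."""

    edges: np.ndarray
    counts: np.ndarray
    total: int

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def __post_init__(self) -> None:
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0) or int(self.counts.sum()) != self.total:
            raise ValueError("histogram counts must be non-negative and sum to the total")


def build_liver_histogram(volume: SUVVolume, liver_mask="liver", bin_width: float = 0.1) -> Histogram:
    """Bin all liver-mask SUVs at fixed width from 0 past the maximum."""
    if isinstance(liver_mask, str):
        liver_mask = volume.mask(liver_mask)
    liver_mask = np.asarray(liver_mask, dtype=bool)
    values = volume.data[liver_mask]
    if values.size == 0:
        raise ValueError("liver mask is empty")
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return Histogram(edges=edges, counts=counts, total=int(values.size))


@dataclass
class MixtureFit:
    """Three Gaussian components fitted to a liver SUV histogram.

    ``components`` holds (weight, mean, sd) sorted by mean; weights are the
    relative component areas and sum to 1.  ``normal_index`` is set by
    :func:`identify_normal_component`.
    """

    components: list[tuple[float, float, float]]
    converged: bool
    gof: float  # root-mean-square residual over sqrt(count) weights
    method: str = "wls"
    normal_index: int | None = None

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])

    def to_json(self) -> dict:
        return {
            "components": [{"weight": w, "mean": m, "sd": s} for w, m, s in self.components],
            "converged": self.converged,
            "gof": self.gof,
            "method": self.method,
            "normal_index": self.normal_index,
        }


def _weighted_quantiles(hist: Histogram, qs) -> np.ndarray:
    cum = np.cumsum(hist.counts) / hist.total
    return np.interp(qs, cum, hist.centers)


def _triple_gauss(x, a1, m1, s1, a2, m2, s2, a3, m3, s3):
    out = np.zeros_like(x)
    for a, m, s in ((a1, m1, s1), (a2, m2, s2), (a3, m3, s3)):
        out = out + a * np.exp(-((x - m) ** 2) / (2.0 * s**2))
    return out


def fit_three_gaussians(hist: Histogram, init: str = "quantile", maxfev: int = 20000) -> MixtureFit:
    """Weighted least-squares fit of three scaled Gaussians to bin counts.

    Initialization (``init="quantile"``): component means at the 10th/50th/
    90th weighted percentiles of the histogram, equal starting widths, and
    amplitudes read off the counts — fully deterministic, so identical
    histograms give identical fits.  Residuals are weighted by
    ``1/sqrt(max(count, 1))`` (Poisson).  Non-convergence returns the best
    iterate flagged ``converged=False``.
    """
    if int(np.count_nonzero(hist.counts)) < 3:
        raise ValueError("histogram has fewer than 3 non-empty bins; cannot fit three components")
    if hist.total < 100:
        raise ValueError(f"histogram total count {hist.total} < 100; fit would be meaningless")
    if init != "quantile":
        raise ValueError(f"unknown init rule {init!r}")
    x = hist.centers
    y = hist.counts.astype(float)
    q10, q50, q90 = _weighted_quantiles(hist, [0.10, 0.50, 0.90])
    spread = max((q90 - q10) / 6.0, hist.bin_width)
    p0 = []
    for m in (q10, q50, q90):
        a0 = max(float(y[np.argmin(np.abs(x - m))]), 1.0)
        p0.extend([a0, m, spread])
    lo = [0.0, float(hist.edges[0]), hist.bin_width / 2.0] * 3
    hi = [float(y.max()) * 10.0 + 10.0, float(hist.edges[-1]), float(hist.edges[-1])] * 3
    sigma = np.sqrt(np.maximum(y, 1.0))

    def residuals(p):
        return (_triple_gauss(x, *p) - y) / sigma

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = least_squares(residuals, p0, bounds=(lo, hi), max_nfev=maxfev)
    converged = bool(res.status > 0)
    if not converged:
        logger.warning("three-Gaussian fit did not converge; returning best iterate")
    popt = res.x
    resid = residuals(popt)
    gof = float(np.sqrt(np.mean(resid**2)))
    comps = []
    for k in range(3):
        a, m, s = popt[3 * k : 3 * k + 3]
        comps.append((float(a * s * np.sqrt(2 * np.pi)), float(m), float(s)))
    total_area = sum(c[0] for c in comps)
    comps = sorted(((area / total_area, m, s) for area, m, s in comps), key=lambda c: c[1])
    return MixtureFit(components=comps, converged=converged, gof=gof, method="wls")


def fit_three_gaussians_em(values: np.ndarray, seed: int = 0) -> MixtureFit:
    """Expectation-maximization alternative on raw voxel values.

    Backed by scikit-learn's Gaussian mixture with deterministic
    quantile-based initialization; used as an independent cross-check of
    the histogram fit.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=float).reshape(-1, 1)
    if values.size < 100:
        raise ValueError("need at least 100 values for the EM fit")
    means_init = np.quantile(values, [0.10, 0.50, 0.90]).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=3, covariance_type="full", means_init=means_init,
        weights_init=np.full(3, 1 / 3), precisions_init=np.ones((3, 1, 1)),
        random_state=seed, n_init=1, max_iter=500,
    )
    gm.fit(values)
    comps = sorted(
        zip(gm.weights_.tolist(), gm.means_.ravel().tolist(), np.sqrt(gm.covariances_.ravel()).tolist()),
        key=lambda c: c[1],
    )
    return MixtureFit(components=[tuple(map(float, c)) for c in comps], converged=bool(gm.converged_), gof=float("nan"), method="em")


def identify_normal_component(fit: MixtureFit, override: int | None = None) -> int:
    """Pick the normal-parenchyma component (middle mean by default).

    The ordering assumption is blood pool < normal parenchyma < tumour.  A
    manual override index wins when supplied (the study's visual selection
    step); equal means tie-break toward the larger weight, logged.
    """
    n = len(fit.components)
    if override is not None:
        if not (0 <= override < n):
            raise ValueError(f"normal-component override {override} out of range 0..{n - 1}")
        fit.normal_index = override
        return override
    order = sorted(range(n), key=lambda k: fit.components[k][1])
    mid = order[n // 2]
    tied = [k for k in range(n) if fit.components[k][1] == fit.components[mid][1]]
    if len(tied) > 1:
        logger.info("tied component means; tie broken toward larger weight")
        mid = max(tied, key=lambda k: fit.components[k][0])
    fit.normal_index = mid
    return mid


def liver_tumour_volume(volume: SUVVolume, liver_mask, fit: MixtureFit) -> tuple[float, np.ndarray]:
    """Liver tumour volume under the mu_normal + sigma_normal rule.

    Tumour voxels are liver-mask voxels with SUV strictly above the
    normal-component mean plus one SD; returns (mL, boolean mask).
    """
    if fit.normal_index is None:
        raise ValueError("normal component not identified; call identify_normal_component first")
    if isinstance(liver_mask, str):
        liver_mask = volume.mask(liver_mask)
    liver_mask = np.asarray(liver_mask, dtype=bool)
    _, mu, sd = fit.components[fit.normal_index]
    tumour = liver_mask & (volume.data > mu + sd)
    return float(tumour.sum()) * volume.voxel_volume_ml, tumour


@dataclass
class VolumeReport:
    """Tumour load per compartment; total = bone + soft tissue + liver."""

    bone_ml: float
    soft_tissue_ml: float
    liver_ml: float

    @property
    def total_ml(self) -> float:
        return self.bone_ml + self.soft_tissue_ml + self.liver_ml

    def to_json(self) -> dict:
        return {
            "bone_ml": self.bone_ml,
            "soft_tissue_ml": self.soft_tissue_ml,
            "liver_ml": self.liver_ml,
            "total_ml": self.total_ml,
        }


def compile_volume_report(
    liver_ml: float,
    lesion_segments: list[LesionSegment] = (),
    compartments: list[str] = (),
) -> VolumeReport:
    """Sum lesion volumes per compartment and add the liver method's volume."""
    if len(lesion_segments) != len(compartments):
        raise ValueError("one compartment label per lesion segment is required")
    sums = {"bone": 0.0, "soft_tissue": 0.0}
    for seg, label in zip(lesion_segments, compartments):
        if label not in sums:
            raise ValueError(f"unknown compartment label {label!r} (use 'bone' or 'soft_tissue')")
        sums[label] += seg.volume_ml
    if liver_ml < 0:
        raise ValueError("liver volume must be non-negative")
    return VolumeReport(bone_ml=sums["bone"], soft_tissue_ml=sums["soft_tissue"], liver_ml=liver_ml)
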