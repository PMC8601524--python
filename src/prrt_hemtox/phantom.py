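"""Synthetic somatostatin-receptor PET phantoms.

The phantom emulates the imaging substrate of the liver-histogram
segmentation method: liver voxels are drawn from a three-component Gaussian
mixture (blood pool / normal parenchyma / tumour), with the tumour component
realised as spatially contiguous blobs so that volume accounting is
meaningful; focal extra-hepatic (bone / soft-tissue) lesions sit as uptake
plateaus on a low noisy background.

No PET physics is modelled (no point-spread function, partial-volume effect
or reconstruction noise correlation): voxel values are independent draws
given their tissue class.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from .volumes import SUVVolume

__all__ = [
    "ExtraLesion",
    "PhantomSpec",
    "generate_phantom",
    "expected_tumour_fraction",
    "expected_liver_tumour_volume_ml",
]


@dataclass(frozen=True)
class ExtraLesion:
    """A focal extra-hepatic lesion: an ellipsoidal SUV plateau.

    ``center_mm`` and ``semiaxes_mm`` are in physical mm; ``suv`` is the
    plateau level; ``compartment`` is ``"bone"`` or ``"soft_tissue"``.
    """

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    suv: float
    compartment: str = "soft_tissue"


def _default_lesions() -> tuple[ExtraLesion, ...]:
    return (
        ExtraLesion(center_mm=(20.0, 20.0, 20.0), semiaxes_mm=(9.0, 8.0, 7.0), suv=12.0, compartment="bone"),
        ExtraLesion(center_mm=(104.0, 104.0, 20.0), semiaxes_mm=(11.0, 9.0, 8.0), suv=9.0, compartment="soft_tissue"),
    )


@dataclass
class PhantomSpec:
    """Parameters of the synthetic PET phantom.

    The liver is an ellipsoid; its voxels are drawn from the mixture
    ``w_b N(mu_b, sd_b) + w_n N(mu_n, sd_n) + w_t N(mu_t, sd_t)`` (SUV units,
    draws clipped at 0).  Tumour voxels are confined to ``n_tumour_blobs``
    disjoint spheres inside the liver; when ``blob_radii_mm`` is None the
    relative radii ``(1, 0.85, 0.7, ...)`` are rescaled so the total blob
    volume equals ``w_t`` times the liver volume, which makes the empirical
    component proportions converge to the nominal weights.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    liver_center_mm: tuple[float, float, float] | None = None  # None -> grid center
    liver_semiaxes_mm: tuple[float, float, float] = (50.0, 48.0, 40.0)
    weights: tuple[float, float, float] = (0.1, 0.7, 0.2)  # (blood pool, normal, tumour)
    means: tuple[float, float, float] = (1.5, 5.0, 15.0)  # SUV
    sds: tuple[float, float, float] = (0.4, 1.0, 4.0)  # SUV
    n_tumour_blobs: int = 3
    blob_radii_mm: tuple[float, ...] | None = None
    lesions: tuple[ExtraLesion, ...] = field(default_factory=_default_lesions)
    background_suv: float = 0.5
    background_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.weights
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w}")
        if any(x < 0 for x in w):
            raise ValueError(f"mixture weights must be non-negative, got {w}")
        if not (self.means[0] < self.means[1] < self.means[2]):
            raise ValueError(f"component means must be ordered blood pool < normal < tumour, got {self.means}")
        if any(s <= 0 for s in self.sds):
            raise ValueError(f"component SDs must be positive, got {self.sds}")
        if any(m < 0 for m in self.means) or self.background_suv < 0:
            raise ValueError("SUV levels must be non-negative")
        if any(s <= 0 for s in self.spacing) or any(a <= 0 for a in self.liver_semiaxes_mm):
            raise ValueError("spacing and liver semi-axes must be positive")

    @property
    def liver_center(self) -> np.ndarray:
        if self.liver_center_mm is not None:
            return np.asarray(self.liver_center_mm, dtype=float)
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    @property
    def liver_volume_mm3(self) -> float:
        a, b, c = self.liver_semiaxes_mm
        return 4.0 / 3.0 * np.pi * a * b * c

    def resolved_blob_radii(self) -> np.ndarray:
        """Absolute blob radii in mm (auto-scaled to w_t when unspecified)."""
        w_t = self.weights[2]
        if self.blob_radii_mm is not None:
            return np.asarray(self.blob_radii_mm, dtype=float)
        if w_t == 0 or self.n_tumour_blobs == 0:
            return np.zeros(0)
        rel = np.array([1.0 * 0.85**i for i in range(self.n_tumour_blobs)])
        target = w_t * self.liver_volume_mm3
        scale = (target / (4.0 / 3.0 * np.pi * np.sum(rel**3))) ** (1.0 / 3.0)
        return rel * scale

    def to_json(self) -> dict:
        d = {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "liver_center_mm": None if self.liver_center_mm is None else list(self.liver_center_mm),
            "liver_semiaxes_mm": list(self.liver_semiaxes_mm),
            "weights": list(self.weights),
            "means": list(self.means),
            "sds": list(self.sds),
            "n_tumour_blobs": self.n_tumour_blobs,
            "blob_radii_mm": None if self.blob_radii_mm is None else list(self.blob_radii_mm),
            "lesions": [
                {
                    "center_mm": list(l.center_mm),
                    "semiaxes_mm": list(l.semiaxes_mm),
                    "suv": l.suv,
                    "compartment": l.compartment,
                }
                for l in self.lesions
            ],
            "background_suv": self.background_suv,
            "background_noise_sd": self.background_noise_sd,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_json(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "lesions" in d:
            d["lesions"] = tuple(
                ExtraLesion(
                    center_mm=tuple(l["center_mm"]),
                    semiaxes_mm=tuple(l["semiaxes_mm"]),
                    suv=float(l["suv"]),
                    compartment=l.get("compartment", "soft_tissue"),
                )
                for l in d["lesions"]
            )
        for key in ("shape", "spacing", "liver_center_mm", "liver_semiaxes_mm", "weights", "means", "sds", "blob_radii_mm"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _voxel_centers_mm(shape: tuple[int, int, int], spacing: tuple[float, float, float]):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(grids, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    q = np.zeros_like(grids[0])
    for g, c, a in zip(grids, center, semiaxes):
        q += ((g - c) / a) ** 2
    return q <= 1.0


def _fibonacci_directions(n: int = 1024) -> np.ndarray:
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


_DIRECTIONS = _fibonacci_directions()


def _sphere_in_ellipsoid(p: np.ndarray, r: float, semi: np.ndarray) -> bool:
    """Support-function test: sphere(p, r) inside the centered ellipsoid.

    Containment holds iff p.u + r <= h_E(u) = sqrt(sum (s_i u_i)^2) for every
    unit direction u; checked over a dense deterministic direction set.
    """
    support = np.sqrt(np.sum((_DIRECTIONS * semi) ** 2, axis=1))
    return bool(np.all(_DIRECTIONS @ p + r <= support))


def _place_blobs(spec: PhantomSpec, radii: np.ndarray, rng: np.random.Generator) -> list[tuple[np.ndarray, float]]:
    """Sample disjoint blob centers fully inside the liver ellipsoid.

    Blobs are placed largest-first by rejection sampling (candidate centers
    uniform in the per-axis shrunk ellipsoid, accepted on the exact
    containment test and non-overlap); the whole placement restarts when a
    blob cannot be fitted next to the already placed ones.
    """
    semi = np.asarray(spec.liver_semiaxes_mm)
    center = spec.liver_center
    order = np.argsort(radii)[::-1]
    for i in order:
        if radii[i] >= semi.min():
            raise ValueError(
                f"tumour blob {i} (radius {radii[i]:.1f} mm) does not fit inside the "
                f"liver ellipsoid with semi-axes {tuple(semi)} mm"
            )
    for _ in range(50):  # placement restarts
        placed: list[tuple[np.ndarray, float]] = []
        ok = True
        for i in order:
            r = float(radii[i])
            shrunk = np.maximum(semi - r, 1e-6)
            for _ in range(500):
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                offset = shrunk * (rng.uniform() ** (1.0 / 3.0) * u)
                if not _sphere_in_ellipsoid(offset, r, semi):
                    continue
                if all(np.linalg.norm(offset + center - c0) > r + r0 for c0, r0 in placed):
                    placed.append((center + offset, r))
                    break
            else:
                ok = False
                break
        if ok:
            # restore the spec's blob order
            by_radius = {round(r, 9): [] for _, r in placed}
            for c, r in placed:
                by_radius[round(r, 9)].append(c)
            out = []
            for i in range(len(radii)):
                out.append((by_radius[round(float(radii[i]), 9)].pop(0), float(radii[i])))
            return out
    raise ValueError(
        f"tumour blobs with radii {np.round(radii, 1).tolist()} mm could not be placed "
        f"disjointly inside the liver ellipsoid"
    )


def generate_phantom(spec: PhantomSpec) -> tuple[SUVVolume, dict]:
    """Generate a phantom volume and its ground-truth record.

    Returns the :class:`SUVVolume` (masks: ``liver``, ``tumour_truth``,
    ``lesion_<i>``) and a truth dict with the mixture parameters, voxelized
    true volumes in mL, and the blob geometry.  Bit-identical for a fixed
    spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    grids = _voxel_centers_mm(spec.shape, spec.spacing)
    semi = np.asarray(spec.liver_semiaxes_mm)
    liver = _ellipsoid_mask(grids, spec.liver_center, semi)
    if not liver.any():
        raise ValueError("liver ellipsoid contains no voxel centers")

    radii = spec.resolved_blob_radii()
    blobs = _place_blobs(spec, radii, rng) if len(radii) else []
    tumour = np.zeros(spec.shape, dtype=bool)
    for cand, r in blobs:
        tumour |= _ellipsoid_mask(grids, cand, np.array([r, r, r]))
    tumour &= liver

    w_b, w_n, _ = spec.weights
    mu = spec.means
    sd = spec.sds
    data = rng.normal(spec.background_suv, spec.background_noise_sd, size=spec.shape)

    nontumour = liver & ~tumour
    n_nt = int(nontumour.sum())
    p_blood = w_b / (w_b + w_n) if (w_b + w_n) > 0 else 0.0
    is_blood = rng.uniform(size=n_nt) < p_blood
    vals = np.where(
        is_blood,
        rng.normal(mu[0], sd[0], size=n_nt),
        rng.normal(mu[1], sd[1], size=n_nt),
    )
    data[nontumour] = vals
    n_t = int(tumour.sum())
    data[tumour] = rng.normal(mu[2], sd[2], size=n_t)

    masks = {"liver": liver, "tumour_truth": tumour}
    lesion_info = []
    for i, les in enumerate(spec.lesions):
        lm = _ellipsoid_mask(grids, np.asarray(les.center_mm), np.asarray(les.semiaxes_mm))
        lm &= ~liver
        data[lm] = rng.normal(les.suv, spec.background_noise_sd, size=int(lm.sum()))
        masks[f"lesion_{i}"] = lm
        a, b, c = les.semiaxes_mm
        lesion_info.append(
            {
                "name": f"lesion_{i}",
                "compartment": les.compartment,
                "plateau_suv": les.suv,
                "analytic_volume_ml": 4.0 / 3.0 * np.pi * a * b * c / 1000.0,
                "voxel_volume_ml": float(lm.sum()) * float(np.prod(spec.spacing)) / 1000.0,
            }
        )

    np.clip(data, 0.0, None, out=data)
    vol = SUVVolume(data, spec.spacing, masks)
    vox_ml = vol.voxel_volume_ml
    truth = {
        "weights": list(spec.weights),
        "means": list(spec.means),
        "sds": list(spec.sds),
        "liver_voxels": int(liver.sum()),
        "liver_volume_ml": float(liver.sum()) * vox_ml,
        "tumour_voxels": n_t,
        "tumour_volume_ml": n_t * vox_ml,
        "blob_centers_mm": [list(map(float, c)) for c, _ in blobs],
        "blob_radii_mm": [r for _, r in blobs],
        "lesions": lesion_info,
        "expected_threshold_volume_ml": expected_liver_tumour_volume_ml(spec, liver_volume_ml=float(liver.sum()) * vox_ml),
    }
    return vol, truth


def expected_tumour_fraction(spec: PhantomSpec, threshold: float | None = None) -> float:
    """Mixture mass above the tumour threshold ``mu_n + sd_n`` (or given).

    Computed by numeric integration of the generating mixture (voxel draws
    are clipped at 0, so each component contributes its mass above max(thr, 0)
    — the clip moves negative draws to 0, below any positive threshold).
    """
    if threshold is None:
        threshold = spec.means[1] + spec.sds[1]
    frac = 0.0
    for w, m, s in zip(spec.weights, spec.means, spec.sds):
        if w == 0:
            continue
        lo = max(threshold, 0.0)
        hi = max(m + 12 * s, lo + 12 * s)
        val, _ = quad(lambda x: norm.pdf(x, m, s), lo, hi)
        frac += w * val
    return frac


def expected_liver_tumour_volume_ml(
    spec: PhantomSpec, threshold: float | None = None, liver_volume_ml: float | None = None
) -> float:
    """Analytic expectation of the liver tumour volume under the mu+sigma rule."""
    if liver_volume_ml is None:
        liver_volume_ml = spec.liver_volume_mm3 / 1000.0
    return expected_tumour_fraction(spec, threshold) * liver_volume_ml


def write_phantom(spec: PhantomSpec, out_dir: str | os.PathLike) -> dict[str, str]:
    """Generate and write the phantom as NIfTI files plus a truth JSON."""
    vol, truth = generate_phantom(spec)
    paths = vol.save_nifti(out_dir, stem="phantom")
    tp = os.path.join(out_dir, "phantom_truth.json")
    with open(tp, "w") as fh:
        json.dump({"spec": spec.to_json(), "truth": truth}, fh, indent=2, sort_keys=True)
    paths["truth"] = tp
    return paths
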