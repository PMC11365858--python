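"""Synthetic 3-D brain phantoms for exercising the lesion pipeline.

Each phantom is a T1-weighted and a FLAIR-like volume over a shared grid
with four tissue classes (background, CSF/ventricle, cortical GM ribbon,
WM), a ground-truth T2-hyperintensity mask and a ground-truth
T1-hypointensity core mask.  The ventricles are a fixed analytic template:
two mirrored curved tubes that widen toward the posterior end, an
occipital-horn analogue, so periventricular lesions grown from the
ventricular surface expand posteriorly the way confluent MS lesions do.

Intensity conventions
---------------------
T1 contrast ordering is WM > GM > CSF.  Lesion tissue is placed relative
to the *effective* cortical GM statistics (texture plus acquisition
noise): a voxel at offset ``d`` sits at ``gm_mean - d * gm_sd_effective``.
T2-lesion tissue outside the T1 core (the "rim": myelinated hyperintense
tissue) gets a mild offset, the T1 core a deep one; on FLAIR all lesion
voxels are hyperintense relative to WM.  Units are arbitrary -- only
GM-referenced contrasts matter to the threshold formula, which is
scale-free given (mean, SD).

Noise is additive Gaussian per voxel; magnitude (Rician) bias is ignored
at the contrast separations simulated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, ScalarVolume

__all__ = ["PhantomParams", "Phantom", "generate_phantom", "CapacityError",
           "BACKGROUND", "CSF", "GM", "WM"]

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3


class CapacityError(ValueError):
    """Requested lesion volume exceeds the available white matter."""


@dataclass(frozen=True)
class PhantomParams:
    """Generative parameters for one phantom.

    ``t1_core_offset_sd`` / ``t1_rim_offset_sd`` are expressed in units of
    the effective GM SD below the GM mean, so a core at offset 1.7 sits
    exactly at the published k = 1.7 segmentation threshold.
    """

    grid_shape: tuple[int, int, int] = (72, 88, 72)
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gm_mean: float = 70.0
    gm_sd: float = 8.0
    wm_mean: float = 100.0
    wm_sd: float = 6.0
    csf_mean: float = 20.0
    csf_sd: float = 6.0
    noise_sd: float = 6.0
    n_periventricular_lesions: int = 1
    n_focal_lesions: int = 0
    focal_volume_share: float = 0.2
    target_t2_volume_ml: float = 10.0
    t1_core_fraction: float = 0.0
    t1_core_offset_sd: float = 2.5
    t1_rim_offset_sd: float = 0.3
    flair_lesion_boost_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_mm) or len(self.voxel_mm) != 3:
            raise ValueError("voxel_mm must be 3 positive reals")
        if min(self.gm_sd, self.wm_sd, self.csf_sd, self.noise_sd) < 0:
            raise ValueError("intensity SDs must be non-negative")
        if not (self.wm_mean > self.gm_mean > self.csf_mean):
            raise ValueError("T1 contrast ordering requires WM > GM > CSF means")
        if self.target_t2_volume_ml < 0:
            raise ValueError("target_t2_volume_ml must be non-negative")
        if not 0.0 <= self.t1_core_fraction <= 1.0:
            raise ValueError("t1_core_fraction must lie in [0, 1]")
        if self.n_periventricular_lesions < 0 or self.n_focal_lesions < 0:
            raise ValueError("lesion counts must be non-negative")
        if not 0.0 <= self.focal_volume_share < 1.0:
            raise ValueError("focal_volume_share must lie in [0, 1)")

    @property
    def gm_sd_effective(self) -> float:
        """SD of GM voxels as measured (texture plus additive noise)."""
        return float(np.hypot(self.gm_sd, self.noise_sd))

    @property
    def voxel_volume_mm3(self) -> float:
        a, b, c = self.voxel_mm
        return a * b * c


@dataclass
class Phantom:
    t1: ScalarVolume
    flair: ScalarVolume
    tissue_labels: np.ndarray
    truth_t2_mask: BinaryMask
    truth_t1_mask: BinaryMask
    params: PhantomParams

    def tissue_mask(self, label: int) -> BinaryMask:
        return BinaryMask(self.tissue_labels == label, self.t1.voxel_mm, self.t1.space)

    @property
    def gm_mask(self) -> BinaryMask:
        return self.tissue_mask(GM)

    @property
    def wm_mask(self) -> BinaryMask:
        return self.tissue_mask(WM)


def _ventricle_template(shape: tuple[int, int, int]) -> np.ndarray:
    """Two mirrored curved tubes widening posteriorly (occipital horns).

    Axis order: x (left-right), y (anterior -> posterior), z
    (inferior -> superior).
    """
    nx, ny, nz = shape
    cx, cz = (nx - 1) / 2.0, (nz - 1) / 2.0
    y0, y1 = int(0.28 * ny), int(0.74 * ny)
    r_small = max(1.5, 0.035 * min(nx, nz))
    r_large = max(r_small + 1.0, 0.085 * min(nx, nz))
    lateral = 0.13 * nx

    vent = np.zeros(shape, dtype=bool)
    X, Z = np.meshgrid(np.arange(nx), np.arange(nz), indexing="ij")
    for y in range(y0, y1 + 1):
        t = (y - y0) / max(1, (y1 - y0))
        r = r_small + (r_large - r_small) * t ** 2
        zc = cz + 0.02 * nz
        for s in (-1.0, 1.0):
            xc = cx + s * (lateral + 0.05 * nx * t)
            vent[:, y, :] |= (X - xc) ** 2 + (Z - zc) ** 2 <= r ** 2
    # anterior bridge joining the two horns (foramina analogue), so the
    # ventricular system -- and lesions grown from its surface -- is one
    # connected structure
    zc = cz + 0.02 * nz
    Yb, Zb = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    bridge_yz = (Yb - y0) ** 2 + (Zb - zc) ** 2 <= r_small ** 2
    x_lo, x_hi = int(np.floor(cx - lateral)), int(np.ceil(cx + lateral))
    vent[x_lo:x_hi + 1, :, :] |= bridge_yz[None, :, :]
    return vent


def _tissue_labels(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Label grid plus the posteriorness weight map used for lesion growth."""
    nx, ny, nz = shape
    c = (np.array(shape) - 1) / 2.0
    semi = 0.44 * np.array(shape)
    X, Y, Z = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    brain = (((X - c[0]) / semi[0]) ** 2 + ((Y - c[1]) / semi[1]) ** 2
             + ((Z - c[2]) / semi[2]) ** 2) <= 1.0
    interior = ndimage.binary_erosion(brain, iterations=3)
    vent = _ventricle_template(shape) & interior

    labels = np.full(shape, BACKGROUND, dtype=np.uint8)
    labels[brain] = GM
    labels[interior] = WM
    labels[vent] = CSF
    return labels, vent


def _horn_tip_seeds(vent: np.ndarray, n_lesions: int) -> np.ndarray:
    """Compact seed regions at the posterior (occipital-horn) tips.

    One requested periventricular lesion seeds at the left horn tip; a
    second adds the right tip; further requests re-use the tips (the caps
    merge into the same confluent complex as they grow).
    """
    idx = np.argwhere(vent)
    y_max = idx[:, 1].max()
    tip_band = idx[idx[:, 1] >= y_max - 3]
    x_mid = np.median(idx[:, 0])
    sides = [tip_band[tip_band[:, 0] <= x_mid], tip_band[tip_band[:, 0] > x_mid]]
    seed = np.zeros_like(vent)
    for i in range(max(1, min(n_lesions, 2))):
        pts = sides[i % 2]
        seed[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    return seed


def _grow_from_surface(eff_dist: np.ndarray, allowed: np.ndarray,
                       seed_region: np.ndarray, n_target: int) -> np.ndarray:
    """Select ~n_target allowed voxels contiguous with the seed region,
    preferring small effective distance.

    Finds the smallest effective-distance level set whose seed-connected
    part reaches n_target, then trims the farthest voxels back to the
    exact count.
    """
    d = np.where(allowed, eff_dist, np.inf)
    finite = d[np.isfinite(d)]
    if finite.size < n_target:
        raise CapacityError("not enough eligible voxels for requested lesion volume")
    # distance level that (ignoring connectivity) contains n_target voxels
    lo = np.partition(finite, n_target - 1)[n_target - 1]
    hi = float(finite.max())

    def connected_at(tau: float) -> np.ndarray:
        cand = d <= tau
        reach = ndimage.binary_propagation(seed_region, mask=cand | seed_region)
        return reach & cand

    sel = connected_at(lo)
    tau_lo, tau_hi = lo, hi
    if sel.sum() < n_target:
        # grow the level until the connected part is large enough
        for _ in range(60):
            mid = 0.5 * (tau_lo + tau_hi)
            sel_mid = connected_at(mid)
            if sel_mid.sum() >= n_target:
                tau_hi, sel = mid, sel_mid
            else:
                tau_lo = mid
            if tau_hi - tau_lo < 1e-6:
                break
        if sel.sum() < n_target:
            sel = connected_at(hi)
            if sel.sum() < n_target:
                raise CapacityError(
                    "requested lesion volume exceeds WM reachable from the seed")
    # trim outermost voxels to the exact target count
    excess = int(sel.sum()) - n_target
    if excess > 0:
        dv = d[sel]
        order = np.argsort(dv, kind="stable")
        keep_flat = np.zeros(dv.size, dtype=bool)
        keep_flat[order[:n_target]] = True
        out = np.zeros_like(sel)
        out[sel] = keep_flat
        sel = out
    # trimming can strand voxels; keep the seed-connected part and regrow
    # shell by shell (nearest eligible frontier voxels first) to the count
    reach = ndimage.binary_propagation(seed_region, mask=sel | seed_region) & sel
    while int(reach.sum()) < n_target:
        frontier = ndimage.binary_dilation(reach | seed_region,
                                           structure=np.ones((3, 3, 3), bool))
        frontier &= allowed & ~reach
        if not frontier.any():
            raise CapacityError(
                "requested lesion volume exceeds WM reachable from the seed")
        need = n_target - int(reach.sum())
        dv = np.where(frontier, d, np.inf).ravel()
        order = np.argsort(dv, kind="stable")[:need]
        add = np.zeros(dv.size, dtype=bool)
        add[order] = True
        reach |= add.reshape(reach.shape)
    return reach


def _place_focal(rng, wm: np.ndarray, forbidden: np.ndarray,
                 vent_dist: np.ndarray, n_lesions: int,
                 n_vox_total: int) -> np.ndarray:
    """Spherical focal lesions away from the ventricles."""
    out = np.zeros_like(wm)
    if n_lesions == 0 or n_vox_total == 0:
        return out
    per = max(1, n_vox_total // n_lesions)
    candidates = np.argwhere(wm & ~forbidden & (vent_dist > 8.0))
    if candidates.size == 0:
        raise CapacityError("no WM available for focal lesions")
    for i in range(n_lesions):
        n_this = per if i < n_lesions - 1 else n_vox_total - per * (n_lesions - 1)
        for _attempt in range(50):
            cx, cy, cz = candidates[rng.integers(len(candidates))]
            r = int(np.ceil((3 * n_this / (4 * np.pi)) ** (1 / 3))) + 2
            sl = tuple(slice(max(0, c - r - 3), c + r + 4) for c in (cx, cy, cz))
            taken = ndimage.binary_dilation(forbidden[sl] | out[sl], iterations=2,
                                            structure=np.ones((3, 3, 3), bool))
            local_ok = wm[sl] & ~taken
            gx, gy, gz = np.meshgrid(*(np.arange(s.start, s.stop) for s in sl),
                                     indexing="ij")
            dist2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
            dist2 = np.where(local_ok, dist2, np.inf)
            flat = dist2.ravel()
            if np.isfinite(flat).sum() < n_this:
                continue
            order = np.argsort(flat, kind="stable")[:n_this]
            pick = np.zeros(flat.size, dtype=bool)
            pick[order] = True
            out[sl] |= pick.reshape(dist2.shape)
            break
        else:
            raise CapacityError("could not place focal lesion in WM")
    return out


def generate_phantom(params: PhantomParams) -> Phantom:
    """Build one phantom deterministically from ``params.seed``.

    The realized T2 mask hits the requested voxel count exactly (rounded
    from ml), the periventricular component is contiguous with the
    ventricular surface and expands posteriorly, and the T1 core occupies
    ``t1_core_fraction`` of the T2 mask (rounded to whole voxels), grown
    outward from the ventricular surface.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(int(s) for s in params.grid_shape)
    labels, vent = _tissue_labels(shape)
    wm = labels == WM
    n_wm = int(wm.sum())

    n_target = int(round(params.target_t2_volume_ml * 1000.0 / params.voxel_volume_mm3))
    if n_target > 0.9 * n_wm:
        raise CapacityError(
            f"target T2 volume needs {n_target} voxels but only {n_wm} WM voxels exist")

    # Euclidean distance from the ventricular surface, shrunk posteriorly so
    # equal-cost growth expands at the occipital-horn end.
    vent_dist = ndimage.distance_transform_edt(~vent, sampling=params.voxel_mm)
    ny = shape[1]
    y = np.arange(ny)
    posteriorness = np.clip((y - 0.28 * ny) / (0.74 * ny - 0.28 * ny), 0.0, 1.0)
    eff = vent_dist * (1.0 - 0.45 * posteriorness)[None, :, None]

    t2 = np.zeros(shape, dtype=bool)
    if n_target > 0:
        n_focal = 0
        if params.n_focal_lesions > 0:
            n_focal = int(round(params.focal_volume_share * n_target))
        n_peri = n_target - n_focal
        if params.n_periventricular_lesions > 0 and n_peri > 0:
            # growth is seeded at occipital-horn tips (alternating sides) so
            # a single requested lesion is one confluent posterior complex
            seed = _horn_tip_seeds(vent, params.n_periventricular_lesions)
            seed_dist = ndimage.distance_transform_edt(~seed,
                                                       sampling=params.voxel_mm)
            eff_seed = seed_dist * (1.0 - 0.45 * posteriorness)[None, :, None]
            t2 |= _grow_from_surface(eff_seed, wm, seed, n_peri)
        elif n_peri > 0:
            n_focal = n_target  # no periventricular component requested
        if n_focal > 0:
            t2 |= _place_focal(rng, wm, t2, vent_dist, max(1, params.n_focal_lesions),
                               n_focal)

    # T1 core: innermost (ventricle-nearest) share of the T2 mask
    n_core = int(round(params.t1_core_fraction * int(t2.sum())))
    t1core = np.zeros(shape, dtype=bool)
    if n_core > 0:
        dv = np.where(t2, vent_dist, np.inf).ravel()
        order = np.argsort(dv, kind="stable")[:n_core]
        flat = np.zeros(dv.size, dtype=bool)
        flat[order] = True
        t1core = flat.reshape(shape)

    # ---- intensities ----
    sd_ref = params.gm_sd_effective
    t1_img = np.zeros(shape)
    flair_img = np.zeros(shape)
    for lab, (m_t1, s_t1) in {
        CSF: (params.csf_mean, params.csf_sd),
        GM: (params.gm_mean, params.gm_sd),
        WM: (params.wm_mean, params.wm_sd),
    }.items():
        sel = labels == lab
        n = int(sel.sum())
        t1_img[sel] = m_t1 + s_t1 * rng.standard_normal(n)
    flair_img[labels == WM] = params.wm_mean + params.wm_sd * rng.standard_normal(
        int((labels == WM).sum()))
    flair_img[labels == GM] = params.wm_mean + params.wm_sd * rng.standard_normal(
        int((labels == GM).sum()))
    flair_img[labels == CSF] = params.csf_mean + params.csf_sd * rng.standard_normal(
        int((labels == CSF).sum()))

    rim = t2 & ~t1core
    t1_img[rim] = params.gm_mean - params.t1_rim_offset_sd * sd_ref
    t1_img[t1core] = params.gm_mean - params.t1_core_offset_sd * sd_ref
    wm_sd_eff = float(np.hypot(params.wm_sd, params.noise_sd))
    flair_img[t2] = params.wm_mean + params.flair_lesion_boost_sd * wm_sd_eff

    if params.noise_sd > 0:
        t1_img += params.noise_sd * rng.standard_normal(shape)
        flair_img += params.noise_sd * rng.standard_normal(shape)

    vm = params.voxel_mm
    return Phantom(
        t1=ScalarVolume(t1_img, vm, "phantom"),
        flair=ScalarVolume(flair_img, vm, "phantom"),
        tissue_labels=labels,
        truth_t2_mask=BinaryMask(t2, vm, "phantom"),
        truth_t1_mask=BinaryMask(t1core, vm, "phantom"),
        params=params,
    )
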