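"""Synthetic serial-section phantoms and lymph-node images with known ground truth.

Raw slide scans for this kind of experiment are rarely deposited publicly,
so every downstream stage is exercised on phantoms generated here: a stack
of horizontal brain sections carrying a brain-shaped mask, a tracer field
that is
either isotropically diffusive around the injection site (the "sacrificed"
pattern) or advective along a branching vessel/fiber-tract skeleton reaching
the contralateral hemisphere (the "living" pattern), per-slice rigid
misalignment emulating mounting jitter, and 2-D lymph-node images containing
true tracer particles (green-only) and autofluorescent particles (equally
bright in green and red).

All generators are pure functions of their spec, including the seed.
Geometry defaults follow the acquisition the pipeline targets: 10.4 um/pixel
in-plane, 70 um slice thickness for brain stacks; 0.65 um/pixel for
lymph-node exports.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "LymphNodeTruth",
    "brain_mask",
    "generate_vessel_tree",
    "simulate_diffusive_tracer",
    "simulate_advective_tracer",
    "render_slices",
    "generate_lymphnode_image",
    "write_slice_stack",
]

BRAIN_PIXEL_UM = 10.4
BRAIN_SLICE_UM = 70.0
NODE_PIXEL_UM = 0.65


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a serial-section brain phantom.

    Attributes
    ----------
    shape : (slices, rows, cols) voxel grid.
    in_plane_um, axial_um : voxel spacing in micrometres.
    injection_center : (slice, row, col) voxel; defaults to the centre of the
        left hemisphere when None.
    mode : "diffusive" (point-source spread) or "advective" (vessel-tract
        spread reaching the contralateral hemisphere).
    diffusion_um2_min : diffusion coefficient D in um^2/min.
    time_min : elapsed time t after injection, minutes.
    total_mass : injected tracer mass M (arbitrary units).
    reach_um : arclength of the advective skeleton from the injection site.
    deposit_width_um : Gaussian tube radius of the advective deposit.
    translation_sigma_px, rotation_sigma_deg : per-slice misalignment scales.
    noise_sigma : additive Gaussian intensity noise (8-bit units).
    seed : fully determines the phantom.
    """

    shape: tuple[int, int, int] = (16, 64, 96)
    in_plane_um: float = BRAIN_PIXEL_UM
    axial_um: float = BRAIN_SLICE_UM
    injection_center: tuple[int, int, int] | None = None
    mode: str = "diffusive"
    diffusion_um2_min: float = 150.0
    time_min: float = 30.0
    total_mass: float = 1.0
    reach_um: float = 1500.0
    deposit_width_um: float = 15.0
    n_branches: int = 3
    translation_sigma_px: float = 3.0
    rotation_sigma_deg: float = 1.5
    translation_max_px: float = 10.0
    rotation_max_deg: float = 5.0
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_plane_um <= 0 or self.axial_um <= 0:
            raise ValueError("voxel spacings must be strictly positive")
        if self.time_min < 0:
            raise ValueError("elapsed time must be non-negative")
        if self.mode not in ("diffusive", "advective"):
            raise ValueError(f"unknown spread mode {self.mode!r}")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """(axial, row, col) voxel spacing in um."""
        return (self.axial_um, self.in_plane_um, self.in_plane_um)

    @property
    def voxel_volume_um3(self) -> float:
        return self.axial_um * self.in_plane_um**2

    def resolved_injection_center(self) -> tuple[int, int, int]:
        if self.injection_center is not None:
            return self.injection_center
        k, r, c = self.shape
        return (k // 2, r // 2, c // 2 - c // 4)

    def with_(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Everything a test needs to verify downstream stages without real data."""

    spec: PhantomSpec
    transforms: list  # applied per-slice misalignments (RigidTransform2D)
    field: np.ndarray  # true tracer concentration, (slices, rows, cols)
    mask: np.ndarray  # brain mask, bool
    skeleton: list[np.ndarray]  # vessel polylines, each (n, 3) voxel coords
    clean_tracer: np.ndarray  # quantized noise-free aligned tracer volume

    def positive_counts(self, threshold: float | None = None) -> dict:
        """True tracer-positive voxel count per hemisphere.

        Positivity is defined on the clean (aligned, noise-free) tracer
        volume; the midline column splits hemispheres, with the injection
        side labelled ipsilateral.
        """
        from .segmentation import otsu_threshold

        vol = self.clean_tracer
        if threshold is None:
            hist = np.bincount(vol[self.mask].astype(np.int64).ravel(),
                               minlength=256)
            threshold = otsu_threshold(hist)
        pos = (vol > threshold) & self.mask
        mid = self.spec.shape[2] / 2.0 - 0.5
        cols = np.nonzero(pos)[2]
        inj_col = self.resolved_injection_col()
        left = int(np.sum(cols < mid))
        right = int(np.sum(cols > mid))
        on = int(np.sum(cols == mid))
        if inj_col < mid:
            ipsi, contra = left, right
        else:
            ipsi, contra = right, left
        return {"ipsi": ipsi, "contra": contra, "on_surface": on,
                "total": int(pos.sum()), "threshold": float(threshold)}

    def resolved_injection_col(self) -> int:
        return self.spec.resolved_injection_center()[2]


@dataclass
class LymphNodeTruth:
    """True per-class pixel counts of a synthetic lymph-node image."""

    n_tracer_px: int
    n_autofluor_px: int
    tracer_mask: np.ndarray = field(repr=False, default=None)
    autofluor_mask: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# brain mask
# ---------------------------------------------------------------------------

def brain_mask(spec: PhantomSpec) -> np.ndarray:
    """Ellipsoidal brain mask with a midline notch marking the fissure.

    An ellipse per slice whose semi-axes shrink toward the first/last slice
    (forming an ellipsoid), with a narrow notch removed along the midline
    column over the anterior half so the two hemispheres are visually and
    geometrically unambiguous.
    """
    k, r, c = spec.shape
    zc, rc, cc = (k - 1) / 2.0, (r - 1) / 2.0, (c - 1) / 2.0
    # axial semi-axis extends past the stack so end slices keep substantial
    # tissue area, as a real cutting range does
    az, ar, ac = max(zc, 0.5) / 0.8, rc - 2.0, cc - 2.0
    zz, rr, ccv = np.meshgrid(np.arange(k), np.arange(r), np.arange(c),
                              indexing="ij")
    mask = ((zz - zc) / az) ** 2 + ((rr - rc) / ar) ** 2 \
        + ((ccv - cc) / ac) ** 2 <= 1.0
    # midline notch: anterior half of the rows, ~1.5 px half-width
    notch = (np.abs(ccv - cc) < 1.6) & (rr < rc)
    mask &= ~notch
    return mask


# ---------------------------------------------------------------------------
# vessel skeleton
# ---------------------------------------------------------------------------

def generate_vessel_tree(spec: PhantomSpec) -> list[np.ndarray]:
    """Random branching polyline skeleton from the injection site.

    The trunk performs a biased random walk toward a target deep in the
    contralateral hemisphere; side branches deflect away from the trunk.
    Every vertex is kept inside the brain mask (steps that would exit are
    pulled back toward the mask centroid); the trunk is guaranteed to cross
    the midline. Deterministic per seed.
    """
    mask = brain_mask(spec)
    if not mask.any():
        raise ValueError("degenerate brain mask: no interior voxels")
    rng = np.random.default_rng(spec.seed)
    k, r, c = spec.shape
    start = np.asarray(spec.resolved_injection_center(), dtype=float)
    if not mask[tuple(start.astype(int))]:
        raise ValueError("injection center lies outside the brain mask")
    centroid = np.array(ndimage.center_of_mass(mask))
    mid = c / 2.0 - 0.5
    # contralateral target mirrors the injection column about the midline
    target = start.copy()
    target[2] = 2 * mid - start[2]

    step_um = spec.in_plane_um  # one in-plane voxel per step
    n_steps = max(8, int(spec.reach_um / step_um))
    spacing = np.asarray(spec.spacing)

    def walk(p0: np.ndarray, bias_point: np.ndarray, n: int,
             wobble: float) -> np.ndarray:
        pts = [p0.copy()]
        p = p0.copy()
        for _ in range(n):
            d = bias_point - p
            nd = np.linalg.norm(d)
            d = d / nd if nd > 1e-9 else rng.standard_normal(3)
            step = d + wobble * rng.standard_normal(3)
            step[0] *= 0.15  # mostly in-plane, small axial drift
            step /= max(np.linalg.norm(step), 1e-9)
            cand = p + step
            tries = 0
            while not _inside(mask, cand) and tries < 8:
                cand = p + 0.6 * step + 0.4 * (centroid - p) \
                    / max(np.linalg.norm(centroid - p), 1e-9)
                step = cand - p
                step /= max(np.linalg.norm(step), 1e-9)
                tries += 1
            if not _inside(mask, cand):
                break
            p = cand
            pts.append(p.copy())
        return np.asarray(pts)

    trunk = walk(start, target, n_steps, wobble=0.35)
    polylines = [trunk]
    if len(trunk) > 6:
        for _ in range(max(0, spec.n_branches)):
            i = int(rng.integers(2, len(trunk) - 2))
            bias = trunk[i] + rng.standard_normal(3) * np.array([1.0, 8.0, 8.0])
            bias[2] = trunk[i][2] + rng.choice([-1, 1]) * 10.0
            branch = walk(trunk[i], bias, n_steps // 3, wobble=0.5)
            if len(branch) > 2:
                polylines.append(branch)
    if not (trunk[:, 2] > mid).any() and not (trunk[:, 2] < mid).any():
        raise RuntimeError("degenerate trunk")
    return polylines


def _inside(mask: np.ndarray, p: np.ndarray) -> bool:
    idx = np.round(p).astype(int)
    if (idx < 0).any() or (idx >= np.asarray(mask.shape)).any():
        return False
    return bool(mask[tuple(idx)])


# ---------------------------------------------------------------------------
# tracer fields
# ---------------------------------------------------------------------------

def simulate_diffusive_tracer(spec: PhantomSpec,
                              mask: np.ndarray | None = None) -> np.ndarray:
    """Point-source diffusion field (the "sacrificed" spread pattern).

    The concentration is the free-space 3-D Green's function of the diffusion
    equation, c(r, t) = M (4 pi D t)^{-3/2} exp(-r^2 / (4 D t)), evaluated at
    voxel centres in physical coordinates, restricted to the brain mask and
    renormalized so the masked field integrates to the total mass M. At t = 0
    all mass sits in the injection voxel.
    """
    if spec.diffusion_um2_min <= 0:
        raise ValueError("diffusion coefficient must be positive")
    if mask is None:
        mask = brain_mask(spec)
    k, r, c = spec.shape
    zc, rc, cc = spec.resolved_injection_center()
    field = np.zeros(spec.shape, dtype=float)
    if spec.time_min == 0:
        field[zc, rc, cc] = spec.total_mass / spec.voxel_volume_um3
        return field * mask
    four_dt = 4.0 * spec.diffusion_um2_min * spec.time_min
    z = (np.arange(k) - zc) * spec.axial_um
    y = (np.arange(r) - rc) * spec.in_plane_um
    x = (np.arange(c) - cc) * spec.in_plane_um
    r2 = (z[:, None, None] ** 2 + y[None, :, None] ** 2
          + x[None, None, :] ** 2)
    field = (np.pi * four_dt) ** -1.5 * np.exp(-r2 / four_dt)
    field *= mask
    total = field.sum() * spec.voxel_volume_um3
    if total <= 0:
        raise ValueError("diffusive field vanished inside the mask")
    return field * (spec.total_mass / total)


def simulate_advective_tracer(
    spec: PhantomSpec,
    skeleton: list[np.ndarray] | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Vessel/fiber-tract spread field (the "living" pattern).

    Tracer is deposited as a Gaussian tube of ``deposit_width_um`` around the
    skeleton polylines, with amplitude decaying exponentially in arclength
    from the injection site, plus a small local diffusive component at the
    injection site. Total mass is renormalized to M. Deterministic per seed
    through the skeleton.
    """
    if mask is None:
        mask = brain_mask(spec)
    if skeleton is None:
        skeleton = generate_vessel_tree(spec)
    if not skeleton or all(len(p) == 0 for p in skeleton):
        raise ValueError("empty vessel skeleton")
    spacing = np.asarray(spec.spacing)
    start = np.asarray(spec.resolved_injection_center(), dtype=float)
    decay_um = max(spec.reach_um / 2.0, 1e-9)

    amp = np.zeros(spec.shape, dtype=float)
    for poly in skeleton:
        seg = np.diff(poly, axis=0) * spacing
        arclen = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
        # branch points inherit the trunk arclength via distance to injection
        offset = np.linalg.norm((poly[0] - start) * spacing)
        s = arclen + offset
        idx = np.round(poly).astype(int)
        np.clip(idx, 0, np.asarray(spec.shape) - 1, out=idx)
        vals = np.exp(-s / decay_um)
        for (zz, yy, xx), v in zip(idx, vals):
            if v > amp[zz, yy, xx]:
                amp[zz, yy, xx] = v

    if spec.deposit_width_um > 0:
        sigma_vox = spec.deposit_width_um / spacing
        field = ndimage.gaussian_filter(amp, sigma=sigma_vox)
        blob = np.zeros(spec.shape)
        blob[tuple(start.astype(int))] = 1.0
        blob = ndimage.gaussian_filter(blob, sigma=3.0 * sigma_vox)
    else:
        field = amp
        blob = np.zeros(spec.shape)
        blob[tuple(start.astype(int))] = 1.0
    # local injection-site pool carries ~20% of the deposited mass
    if blob.sum() > 0 and field.sum() > 0:
        field = field + 0.25 * field.sum() / blob.sum() * blob
    field *= mask
    total = field.sum() * spec.voxel_volume_um3
    if total <= 0:
        raise ValueError("advective field vanished inside the mask")
    return field * (spec.total_mass / total)


def simulate_tracer(spec: PhantomSpec,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Dispatch on ``spec.mode``."""
    if spec.mode == "diffusive":
        return simulate_diffusive_tracer(spec, mask=mask)
    return simulate_advective_tracer(spec, mask=mask)


# ---------------------------------------------------------------------------
# slice rendering
# ---------------------------------------------------------------------------

def render_slices(
    field: np.ndarray,
    spec: PhantomSpec,
    quantize: bool = True,
    skeleton: list[np.ndarray] | None = None,
) -> tuple[list[dict[str, np.ndarray]], GroundTruth]:
    """Section the volume into misaligned multichannel slice images.

    Each axial plane becomes one slice with channels ``nuclei`` (a smooth
    random texture inside the brain mask, correlated across slices so that
    rigid registration is well-posed) and ``tracer`` (the field plane scaled
    to 8-bit). Every slice is independently perturbed by a rigid transform
    drawn from the spec's zero-mean misalignment scales; the applied true
    transforms are recorded in the returned GroundTruth.
    """
    from .registration import RigidTransform2D

    if field.shape != spec.shape:
        raise ValueError("field shape does not match spec")
    mask = brain_mask(spec)
    rng = np.random.default_rng(spec.seed + 1)

    # nuclei texture: a dominant columnar (slice-shared) component — the
    # coarse anatomy that makes serial-section registration well-posed —
    # plus fine per-slice detail emulating slice-to-slice cellular variation
    smooth = ndimage.gaussian_filter(rng.standard_normal(spec.shape[1:]), 3.0)
    edges = np.quantile(smooth, [0.25, 0.5, 0.75])
    bands = np.digitize(smooth, edges).astype(float)
    bands = ndimage.gaussian_filter(bands, 0.7)
    bands = (bands - bands.mean()) / max(bands.std(), 1e-12)
    grain = ndimage.gaussian_filter(rng.standard_normal(spec.shape[1:]), 0.8)
    grain /= max(grain.std(), 1e-12)
    detail = ndimage.gaussian_filter(rng.standard_normal(spec.shape),
                                     sigma=(2.0, 0.8, 0.8))
    detail /= max(detail.std(), 1e-12)
    tex = (0.8 * bands + 0.5 * grain)[None, :, :] + 0.15 * detail
    tex = (tex - tex.min()) / max(np.ptp(tex), 1e-12)
    nuclei = (40.0 + 150.0 * tex) * mask

    fmax = field.max()
    tracer = field / fmax * 230.0 if fmax > 0 else np.zeros_like(field)
    tracer = tracer * mask
    if quantize:
        nuclei = np.round(nuclei)
        tracer = np.round(tracer)
    clean_tracer = tracer.copy()

    slices: list[dict[str, np.ndarray]] = []
    transforms = []
    tmax, rmax = spec.translation_max_px, spec.rotation_max_deg
    for z in range(spec.shape[0]):
        # zero-mean mounting jitter, bounded as physical slide placement is
        angle = float(np.clip(rng.normal(0.0, spec.rotation_sigma_deg),
                              -rmax, rmax))
        dx = float(np.clip(rng.normal(0.0, spec.translation_sigma_px),
                           -tmax, tmax))
        dy = float(np.clip(rng.normal(0.0, spec.translation_sigma_px),
                           -tmax, tmax))
        if spec.rotation_sigma_deg == 0:
            angle = 0.0
        if spec.translation_sigma_px == 0:
            dx = dy = 0.0
        t = RigidTransform2D(angle_deg=angle, dx=dx, dy=dy)
        transforms.append(t)
        sl = {}
        for name, vol in (("nuclei", nuclei), ("tracer", tracer)):
            img = t.warp(vol[z]) if not t.is_identity() else vol[z].copy()
            if spec.noise_sigma > 0:
                img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
            img = np.clip(img, 0.0, 255.0)
            if quantize:
                img = np.round(img)
            sl[name] = img
        slices.append(sl)

    truth = GroundTruth(spec=spec, transforms=transforms, field=field,
                        mask=mask, skeleton=skeleton or [],
                        clean_tracer=clean_tracer)
    return slices, truth


def make_phantom(spec: PhantomSpec, quantize: bool = True):
    """Convenience: field + slices + truth in one call."""
    mask = brain_mask(spec)
    if spec.mode == "advective":
        skeleton = generate_vessel_tree(spec)
        field = simulate_advective_tracer(spec, skeleton=skeleton, mask=mask)
    else:
        skeleton = []
        field = simulate_diffusive_tracer(spec, mask=mask)
    slices, truth = render_slices(field, spec, quantize=quantize,
                                  skeleton=skeleton)
    return slices, truth


# ---------------------------------------------------------------------------
# lymph-node images
# ---------------------------------------------------------------------------

def generate_lymphnode_image(
    n_tracer: int,
    n_autofluor: int,
    particle_radius_px: int = 3,
    seed: int = 0,
    shape: tuple[int, int] = (192, 192),
    tracer_brightness: float = 200.0,
    autofluor_brightness: float = 160.0,
    red_gain: float = 1.0,
    noise_sigma: float = 3.0,
    background: float = 8.0,
    max_retries: int = 2000,
) -> tuple[np.ndarray, LymphNodeTruth]:
    """Synthetic 3-channel lymph-node raster with known particle counts.

    Tracer particles are bright in green only; autofluorescent particles are
    equally bright in green and red (red then scaled by ``red_gain`` to
    emulate exposure differences between channels); a nuclei texture fills
    the blue channel. Returns an (H, W, 3) float image with channel order
    (red, green, blue) and the true per-class pixel counts.
    """
    if n_tracer < 0 or n_autofluor < 0:
        raise ValueError("particle counts must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    node = (((yy - (h - 1) / 2) / (h / 2 - 4)) ** 2
            + ((xx - (w - 1) / 2) / (w / 2 - 4)) ** 2) <= 1.0

    def place(n: int) -> list[tuple[int, int]]:
        centers: list[tuple[int, int]] = []
        tries = 0
        while len(centers) < n:
            if tries > max_retries:
                raise RuntimeError(
                    "could not place particles without overlap after "
                    f"{max_retries} retries")
            cy = int(rng.integers(particle_radius_px, h - particle_radius_px))
            cx = int(rng.integers(particle_radius_px, w - particle_radius_px))
            tries += 1
            if not node[cy, cx]:
                continue
            if all((cy - oy) ** 2 + (cx - ox) ** 2
                   > (2 * particle_radius_px + 2) ** 2
                   for oy, ox in placed):
                centers.append((cy, cx))
                placed.append((cy, cx))
        return centers

    placed: list[tuple[int, int]] = []
    tracer_centers = place(n_tracer)
    auto_centers = place(n_autofluor)

    def disc_mask(centers) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        for cy, cx in centers:
            m |= (yy - cy) ** 2 + (xx - cx) ** 2 <= particle_radius_px ** 2
        return m

    tracer_mask = disc_mask(tracer_centers)
    auto_mask = disc_mask(auto_centers)

    green = np.full(shape, background, dtype=float) * node
    red = np.full(shape, background, dtype=float) * node
    green[tracer_mask] = tracer_brightness
    green[auto_mask] = autofluor_brightness
    red[auto_mask] = autofluor_brightness
    red *= red_gain

    blue_tex = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    blue_tex = (blue_tex - blue_tex.min()) / max(np.ptp(blue_tex), 1e-12)
    blue = (30.0 + 120.0 * blue_tex) * node

    img = np.stack([red, green, blue], axis=-1)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(np.round(img), 0.0, 255.0)

    truth = LymphNodeTruth(
        n_tracer_px=int(tracer_mask.sum()),
        n_autofluor_px=int(auto_mask.sum()),
        tracer_mask=tracer_mask,
        autofluor_mask=auto_mask,
    )
    return img, truth


# ---------------------------------------------------------------------------
# on-disk export
# ---------------------------------------------------------------------------

def write_slice_stack(slices: list[dict[str, np.ndarray]],
                      truth: GroundTruth, outdir: str,
                      fmt: str = "tiff") -> str:
    """Write numbered slice files plus ground-truth sidecars.

    One multichannel TIFF (or per-channel PNG) per slice, the applied
    transforms as CSV (slice_index, angle_deg, dx_px, dy_px), and scalar
    truths as JSON. Returns the manifest path.
    """
    import tifffile
    import imageio.v3 as iio

    os.makedirs(outdir, exist_ok=True)
    channel_names = list(slices[0].keys())
    entries = []
    for i, sl in enumerate(slices):
        if fmt == "tiff":
            path = os.path.join(outdir, f"slice_{i:03d}.tif")
            tifffile.imwrite(path, np.stack(
                [sl[c].astype(np.uint8) for c in channel_names]))
            entries.append({"path": os.path.basename(path), "slice_index": i})
        else:
            for c in channel_names:
                path = os.path.join(outdir, f"slice_{i:03d}_{c}.png")
                iio.imwrite(path, sl[c].astype(np.uint8))
            entries.append({"path": f"slice_{i:03d}_{{channel}}.png",
                            "slice_index": i})
    pd.DataFrame(
        [{"slice_index": i, "angle_deg": t.angle_deg,
          "dx_px": t.dx, "dy_px": t.dy}
         for i, t in enumerate(truth.transforms)]
    ).to_csv(os.path.join(outdir, "true_transforms.csv"), index=False)
    counts = truth.positive_counts()
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump({"positive_counts": counts,
                   "seed": truth.spec.seed,
                   "mode": truth.spec.mode}, fh, indent=2)
    manifest = {
        "format": fmt,
        "channels": channel_names,
        "in_plane_um": truth.spec.in_plane_um,
        "axial_um": truth.spec.axial_um,
        "slices": entries,
    }
    mpath = os.path.join(outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return mpath
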