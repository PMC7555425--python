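"""Synthetic T2W-like phantoms, observer masks and graded mask perturbations.

The phantom is an ellipsoidal "gland" embedded in a darker background, with
an optional brighter peripheral-zone shell and multiplicative spatially
correlated noise so that texture features take nontrivial, mask-sensitive
values. Morphological perturbations of the gold-standard mask emulate the
quality gradient of automated segmenters, from near-perfect contours to
badly eroded, leaking or truncated ones. All generators are pure functions
of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imaging import ImageVolume, SegMask

__all__ = [
    "IntensityParams",
    "PhantomSpec",
    "PerturbationSpec",
    "PhantomCase",
    "generate_phantom",
    "perturb_mask",
    "generate_observer_cohort",
    "METHOD_RECIPES",
    "simulate_method_masks",
]

PERTURBATION_KINDS = (
    "none",
    "erode",
    "dilate",
    "translate",
    "drop_apex_slices",
    "drop_base_slices",
    "leak_blob",
    "boundary_jitter",
)


@dataclass(frozen=True)
class IntensityParams:
    """Mean/SD of the three intensity compartments (arbitrary T2W-like units)."""

    gland_mean: float = 180.0
    gland_sd: float = 25.0
    pz_mean: float = 260.0
    pz_sd: float = 30.0
    background_mean: float = 80.0
    background_sd: float = 12.0
    #: SD of the multiplicative correlated noise field
    mult_noise_sd: float = 0.15


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of one synthetic case.

    ``ellipsoid_center`` is in voxel coordinates, ``ellipsoid_radii`` in mm.
    ``texture_corr_length`` is the spatial correlation length (in voxels) of
    the multiplicative noise. The ellipsoid must fit fully inside the grid.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ellipsoid_center: tuple[float, float, float] = (32.0, 32.0, 32.0)
    ellipsoid_radii: tuple[float, float, float] = (20.0, 25.0, 22.0)
    intensity: IntensityParams = field(default_factory=IntensityParams)
    texture_corr_length: float = 3.0
    pz_shell: bool = True
    seed: int = 0

    def __post_init__(self):
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if any(r <= 0 for r in self.ellipsoid_radii):
            raise ValueError("ellipsoid radii must be positive")
        for c, r, sp, n in zip(
            self.ellipsoid_center, self.ellipsoid_radii, self.spacing, self.grid_shape
        ):
            if c - r / sp < 0 or c + r / sp > n - 1:
                raise ValueError(
                    f"ellipsoid exceeds grid bounds: center {c}, radius "
                    f"{r} mm / {sp} mm spacing on an axis of {n} voxels"
                )


@dataclass(frozen=True)
class PerturbationSpec:
    """One mask perturbation: kind, magnitude (voxels or slices) and seed."""

    kind: str = "none"
    magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(
                f"unknown perturbation {self.kind!r}; options: "
                + ", ".join(PERTURBATION_KINDS)
            )
        if self.magnitude < 0:
            raise ValueError("magnitude must be nonnegative")


@dataclass(frozen=True)
class PhantomCase:
    image: ImageVolume
    gold: SegMask
    observer: SegMask | None = None


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n, dtype=np.float64) for n in spec.grid_shape], indexing="ij"
    )
    rho2 = sum(
        ((g - c) * sp / r) ** 2
        for g, c, sp, r in zip(
            grids, spec.ellipsoid_center, spec.spacing, spec.ellipsoid_radii
        )
    )
    return rho2, rho2 <= 1.0


def _correlated_field(shape, corr_length, rng) -> np.ndarray:
    """Zero-mean, unit-SD Gaussian field with the given correlation length."""
    white = rng.standard_normal(shape)
    if corr_length <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=corr_length)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, SegMask]:
    """Voxelize the ellipsoid and synthesize the surrounding intensities."""
    rng = np.random.default_rng(spec.seed)
    rho2, inside = _ellipsoid_mask(spec)
    p = spec.intensity
    img = rng.normal(p.background_mean, p.background_sd, spec.grid_shape)
    img[inside] = rng.normal(p.gland_mean, p.gland_sd, int(inside.sum()))
    if spec.pz_shell:
        shell = inside & (rho2 >= 0.8**2)
        img[shell] = rng.normal(p.pz_mean, p.pz_sd, int(shell.sum()))
    field = _correlated_field(spec.grid_shape, spec.texture_corr_length, rng)
    img = img * (1.0 + p.mult_noise_sd * field)
    img = np.clip(img, 0.0, None)
    vol = ImageVolume(img, spec.spacing, provenance={"phantom_seed": spec.seed})
    mask = SegMask(inside, spec.spacing)
    return vol, mask


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (x**2 + y**2 + z**2) <= r**2


def _containing_slices(vox: np.ndarray) -> np.ndarray:
    return np.flatnonzero(vox.any(axis=(0, 1)))


def perturb_mask(mask: SegMask, spec: PerturbationSpec) -> SegMask:
    """Apply one graded perturbation; grid and spacing are preserved.

    A perturbation that empties the mask returns an empty mask carrying a
    warning flag rather than raising, because downstream metric code must
    handle empty automated masks anyway.
    """
    if mask.is_empty:
        raise ValueError("cannot perturb an empty mask")
    kind, mag = spec.kind, spec.magnitude
    if kind == "none" or mag == 0:
        return mask
    rng = np.random.default_rng(spec.seed)
    vox = mask.voxels.astype(bool)
    if kind == "erode":
        out = ndimage.binary_erosion(vox, structure=_ball(round(mag)), border_value=0)
    elif kind == "dilate":
        out = ndimage.binary_dilation(vox, structure=_ball(round(mag)))
    elif kind == "translate":
        axis = int(rng.integers(0, 2))  # in-plane axis
        sign = 1 if rng.integers(0, 2) else -1
        shift = [0, 0, 0]
        shift[axis] = sign * round(mag)
        out = np.zeros_like(vox)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        s = shift[axis]
        if s > 0:
            dst[axis], src[axis] = slice(s, None), slice(None, -s)
        else:
            dst[axis], src[axis] = slice(None, s), slice(-s, None)
        out[tuple(dst)] = vox[tuple(src)]
    elif kind in ("drop_apex_slices", "drop_base_slices"):
        out = vox.copy()
        containing = _containing_slices(vox)
        k = min(round(mag), len(containing))
        drop = containing[:k] if kind == "drop_apex_slices" else containing[-k:]
        if k:
            out[:, :, drop] = False
    elif kind == "leak_blob":
        out = vox.copy()
        surf = np.argwhere(
            vox
            & ~ndimage.binary_erosion(
                vox, structure=ndimage.generate_binary_structure(3, 1), border_value=0
            )
        )
        centroid = np.argwhere(vox).mean(axis=0)
        pick = surf[rng.integers(0, len(surf))]
        normal = pick - centroid
        normal = normal / max(np.linalg.norm(normal), 1e-9)
        r = max(round(mag), 1)
        center = np.clip(
            np.round(pick + normal * (r + 1)).astype(int),
            0,
            np.array(vox.shape) - 1,
        )
        grids = np.meshgrid(*[np.arange(n) for n in vox.shape], indexing="ij")
        blob = (
            sum((g - c) ** 2 for g, c in zip(grids, center)) <= r**2
        )
        out |= blob
    elif kind == "boundary_jitter":
        # signed voxel-unit distance to the boundary, positive inside
        d_in = ndimage.distance_transform_edt(vox)
        d_out = ndimage.distance_transform_edt(~vox)
        sdist = d_in - d_out
        noise = _correlated_field(vox.shape, 2.0, rng) * mag
        out = (sdist + noise) > 0
    else:  # pragma: no cover - guarded by PerturbationSpec
        raise ValueError(kind)
    warning = None
    if not out.any():
        warning = f"perturbation {kind} (magnitude {mag}) emptied the mask"
    return replace(mask, voxels=out.astype(np.uint8), warning=warning)


def _case_spec(base: PhantomSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    """Per-case anatomy variation: radii scaled by ~10% within grid bounds."""
    factors = rng.uniform(0.9, 1.1, size=3)
    radii = []
    for r, f, c, sp, n in zip(
        base.ellipsoid_radii,
        factors,
        base.ellipsoid_center,
        base.spacing,
        base.grid_shape,
    ):
        max_r = min(c, n - 1 - c) * sp * 0.999
        radii.append(min(r * f, max_r))
    return replace(base, ellipsoid_radii=tuple(radii), seed=seed)


def generate_observer_cohort(
    n: int,
    phantom_spec: PhantomSpec,
    observer_noise: PerturbationSpec,
    seed: int = 0,
) -> list[PhantomCase]:
    """Simulate the second-observer cohort used to calibrate metric scores.

    Each case is an independently varied phantom whose "observer" mask is
    the gold mask under mild boundary jitter — a stand-in for a second
    expert re-contouring the gland.
    """
    if n < 2:
        raise ValueError("observer cohort needs n >= 2 (calibration uses a mean)")
    root = np.random.SeedSequence(seed)
    cases = []
    for child in root.spawn(n):
        sub = np.random.default_rng(child)
        s1, s2 = int(sub.integers(0, 2**31)), int(sub.integers(0, 2**31))
        spec = _case_spec(phantom_spec, sub, s1)
        image, gold = generate_phantom(spec)
        observer = perturb_mask(gold, replace(observer_noise, seed=s2))
        cases.append(PhantomCase(image, gold, observer))
    return cases


def _recipe_observer_like(rng):
    return [PerturbationSpec("boundary_jitter", float(rng.uniform(0.5, 2.0)))]


def _recipe_undersegment(rng):
    return [
        PerturbationSpec("erode", float(rng.integers(0, 4))),
        PerturbationSpec("boundary_jitter", float(rng.uniform(0.0, 1.0))),
    ]


def _recipe_oversegment(rng):
    return [
        PerturbationSpec("dilate", float(rng.integers(0, 4))),
        PerturbationSpec("boundary_jitter", float(rng.uniform(0.0, 1.0))),
    ]


def _recipe_sloppy(rng):
    specs = [PerturbationSpec("boundary_jitter", float(rng.uniform(1.0, 3.0)))]
    if rng.random() < 0.5:
        specs.append(PerturbationSpec("drop_apex_slices", float(rng.integers(1, 4))))
    if rng.random() < 0.5:
        specs.append(PerturbationSpec("leak_blob", float(rng.integers(2, 5))))
    if rng.random() < 0.3:
        specs.append(PerturbationSpec("translate", float(rng.integers(1, 4))))
    return specs


#: four simulated "segmentation methods" of graded typical quality,
#: emulating the spread of automated segmenters
METHOD_RECIPES = {
    "observer_like": _recipe_observer_like,
    "undersegment": _recipe_undersegment,
    "oversegment": _recipe_oversegment,
    "sloppy": _recipe_sloppy,
}


def simulate_method_masks(
    gold: SegMask, method: str, seed: int
) -> tuple[SegMask, list[PerturbationSpec]]:
    """Produce one simulated automated segmentation of ``gold``."""
    rng = np.random.default_rng(seed)
    specs = METHOD_RECIPES[method](rng)
    out = gold
    applied = []
    for sp in specs:
        sp = replace(sp, seed=int(rng.integers(0, 2**31)))
        if out.is_empty:
            break
        out = perturb_mask(out, sp)
        applied.append(sp)
    return out, applied
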