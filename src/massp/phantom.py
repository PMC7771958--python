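"""Seeded synthetic cohorts: multi-structure label geometry plus
multi-channel intensity volumes with inter-subject variability.

The default phantom emulates, at desk scale, the situation the parcellation
model is built for: a handful of adjacent subcortical structures of very
different sizes and shapes — a large ellipsoid (thalamus-like), a medium
ball sharing an interface with it (striatum-like), a two-shell pair
(internal/external pallidum analogue), a thin curved sheet (claustrum
analogue), a tube (ventricle analogue) and a small ball of under 150 voxels
(subthalamic-nucleus analogue) — imaged in three quantitative channels with
R1-, R2*- and susceptibility-like value ranges. Inter-subject anatomical
variability is a smooth random displacement field; intensity variability is
a per-subject shift of each structure's channel mean plus voxel noise.

Every subject is fully determined by ``(spec.seed, subject_seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import LabelVolume, ScalarVolume, VolumeGrid

__all__ = ["ShapeRecipe", "PhantomSpec", "PhantomSubject", "make_subject", "make_cohort", "default_spec"]


@dataclass(frozen=True)
class ShapeRecipe:
    """One structure: a shape primitive plus per-channel intensity model."""

    structure_id: int
    name: str
    shape: str  # ball | ellipsoid | shell | sheet | tube
    center: tuple[float, float, float]
    radii: tuple[float, ...]  # shape-dependent, voxels
    means: tuple[float, ...]  # per-channel intensity mean
    mean_stds: tuple[float, ...]  # per-channel inter-subject std of the mean


@dataclass(frozen=True)
class PhantomSpec:
    """Cohort-level recipe; rasterization order resolves shape overlaps
    (earlier recipes take priority)."""

    grid_size: int = 64
    voxel_mm: float = 1.0
    recipes: tuple[ShapeRecipe, ...] = ()
    background_mean: tuple[float, ...] = (0.55, 30.0, 0.0)
    background_mean_std: tuple[float, ...] = (0.015, 1.5, 0.003)
    noise_std: tuple[float, ...] = (0.02, 2.0, 0.004)
    deform_amplitude_mm: float = 2.0
    deform_smoothness_mm: float = 8.0
    seed: int = 42

    @property
    def n_channels(self) -> int:
        return len(self.background_mean)

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid.isotropic(self.grid_size, self.voxel_mm)


@dataclass
class PhantomSubject:
    truth: LabelVolume
    contrasts: list[ScalarVolume]
    displacement: np.ndarray  # (3, X, Y, Z) voxel units


def default_spec(seed: int = 42) -> PhantomSpec:
    """The default 64^3, 1 mm isotropic, 3-channel, 7-structure phantom."""
    recipes = (
        ShapeRecipe(1, "ellipsoid_large", "ellipsoid", (22, 32, 32), (9, 7, 7),
                    (0.75, 38.0, 0.012), (0.015, 1.5, 0.003)),
        ShapeRecipe(2, "ball_adjacent", "ball", (37, 32, 32), (6,),
                    (0.65, 45.0, 0.033), (0.015, 1.5, 0.003)),
        ShapeRecipe(3, "shell_inner", "ball", (20, 16, 44), (4,),
                    (0.88, 78.0, 0.100), (0.015, 1.5, 0.003)),
        ShapeRecipe(4, "shell_outer", "shell", (20, 16, 44), (5, 8),
                    (0.85, 88.0, 0.120), (0.015, 1.5, 0.003)),
        ShapeRecipe(5, "sheet_thin", "sheet", (46, 47, 46), (8, 5, 1.0),
                    (0.66, 33.0, -0.012), (0.015, 1.5, 0.003)),
        ShapeRecipe(6, "tube", "tube", (48, 32, 26), (2.5, 18), (0.30, 12.0, 0.010),
                    (0.015, 1.5, 0.003)),
        ShapeRecipe(7, "ball_small", "ball", (52, 20, 52), (3,),
                    (0.95, 70.0, 0.062), (0.015, 1.5, 0.003)),
    )
    return PhantomSpec(recipes=recipes, seed=seed)


def _rasterize(spec: PhantomSpec) -> np.ndarray:
    n = spec.grid_size
    x, y, z = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    labels = np.zeros((n, n, n), dtype=np.int32)
    for r in spec.recipes:
        cx, cy, cz = r.center
        dx, dy, dz = x - cx, y - cy, z - cz
        if r.shape == "ball":
            m = dx * dx + dy * dy + dz * dz <= r.radii[0] ** 2
        elif r.shape == "ellipsoid":
            a, b, c = r.radii
            m = (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0
        elif r.shape == "shell":
            inner, outer = r.radii
            d2 = dx * dx + dy * dy + dz * dz
            m = (d2 > inner**2) & (d2 <= outer**2)
        elif r.shape == "sheet":
            # thin curved sheet: z follows a sine wave over an x-y patch
            ex, ey, half_th = r.radii
            wave = cz + 3.0 * np.sin(2.0 * np.pi * dx / (4.0 * ex))
            m = (np.abs(z - wave) <= half_th) & (np.abs(dx) <= ex) & (np.abs(dy) <= ey)
        elif r.shape == "tube":
            rad, half_len = r.radii
            m = (dx * dx + dz * dz <= rad**2) & (np.abs(dy) <= half_len)
        else:
            raise ValueError(f"unknown shape {r.shape!r}")
        # priority: earlier recipes win overlapping voxels
        labels[m & (labels == 0)] = r.structure_id
    return labels


def _displacement(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.grid_size
    sig = spec.deform_smoothness_mm / spec.voxel_mm
    u = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal((n, n, n)), sig) for _ in range(3)]
    )
    rms = float(np.sqrt((u**2).sum(axis=0).mean()))
    if rms > 0:
        u *= (spec.deform_amplitude_mm / spec.voxel_mm) / rms
    return u


def make_subject(spec: PhantomSpec, subject_seed: int) -> PhantomSubject:
    """One synthetic subject: warped truth labels plus noisy contrasts."""
    if not spec.recipes:
        raise ValueError("phantom spec has no structure recipes")
    for r in spec.recipes:
        if len(r.means) != spec.n_channels:
            raise ValueError("recipe channel count does not match spec")
    rng = np.random.default_rng([spec.seed, subject_seed])
    base = _rasterize(spec)
    u = _displacement(spec, rng)
    n = spec.grid_size
    grid_coords = np.mgrid[0:n, 0:n, 0:n].astype(np.float64)
    warped = ndimage.map_coordinates(
        base, grid_coords + u, order=0, mode="nearest"
    ).astype(np.int32)
    for r in spec.recipes:
        if not (warped == r.structure_id).any():
            raise ValueError(
                f"deformation emptied structure {r.structure_id}; "
                "reduce the amplitude or enlarge the shapes"
            )
    table = {r.structure_id: r.name for r in spec.recipes}
    truth = LabelVolume(spec.grid, warped, table)

    contrasts = []
    for c in range(spec.n_channels):
        img = np.full(
            (n, n, n),
            spec.background_mean[c] + rng.normal(0.0, spec.background_mean_std[c]),
            dtype=np.float64,
        )
        for r in spec.recipes:
            mean_c = r.means[c] + rng.normal(0.0, r.mean_stds[c])
            img[warped == r.structure_id] = mean_c
        img += rng.normal(0.0, spec.noise_std[c], size=img.shape)
        contrasts.append(ScalarVolume(spec.grid, img, "contrast"))
    return PhantomSubject(truth=truth, contrasts=contrasts, displacement=u)


def make_cohort(spec: PhantomSpec, n: int = 10) -> list[PhantomSubject]:
    """n subjects with subject_seed = spec.seed + index (default cohort of
    ten, the usual atlas-building cohort size)."""
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    return [make_subject(spec, spec.seed + i) for i in range(n)]
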