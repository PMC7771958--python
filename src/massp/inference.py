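"""Parcellation inference: voxel-wise posteriors, Markovian diffusion,
topology correction and volume-constrained region growing.

The pipeline assumes the subject's contrast volumes are already co-registered
to the atlas grid (registration is an upstream preprocessing step):

1. **Voxel-wise posteriors** — for each pair kept in the atlas at a voxel,
   posterior = spatial prior x fused intensity likelihood; the interior pair
   i|i competes with the square root of the skeleton prior, which extends
   coverage deep inside each structure.
2. **Markovian diffusion** — a sparse MRF over each voxel and its four most
   intensity-similar 26-neighbors, iterated (synchronous updates, weights
   normalized to sum to one) until the fraction of changed argmax labels in
   the region of interest drops below ``stop_ratio``.
3. **Topology correction** — per-structure max over its pairs, then a
   topology-preserving fast marching so every superlevel set has spherical
   object topology.
4. **Region growing** — target volumes blend the observed volume with the
   log-normal prior; structures grow concurrently from their posterior
   maxima, without overlap, until each reaches its target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .atlas import Atlas
from .grids import LabelVolume, ScalarVolume, check_same_grid
from .topology import grow_regions, topology_correct_field

logger = logging.getLogger(__name__)

__all__ = [
    "PosteriorMap",
    "ParcellationResult",
    "voxelwise_posteriors",
    "similarity_weight",
    "mrf_diffusion",
    "collapse_to_structures",
    "target_volume",
    "parcellate",
]

_OFFSETS26 = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)


@dataclass
class PosteriorMap:
    """Pair-wise posterior values on the region of interest.

    ``values[v, p]`` holds the posterior of pair ``pair_codes[p]`` at region
    voxel ``region_idx[v]``; only slots flagged in ``kept`` are defined (the
    atlas keeps at most K pairs per voxel).
    """

    shape: tuple[int, int, int]
    structure_ids: list[int]
    pair_codes: np.ndarray  # (P,) int64 codes i_idx * S + j_idx
    region_idx: np.ndarray  # (V,) int64 flat voxel indices
    values: np.ndarray  # (V, P) float64
    kept: np.ndarray  # (V, P) bool
    n_iter: int = 0
    trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def n_structures(self) -> int:
        return len(self.structure_ids)

    def argmax_structure(self) -> np.ndarray:
        """Per region voxel, the structure index of the maximal pair (-1 if
        no positive entry)."""
        vals = np.where(self.kept, self.values, -np.inf)
        best = np.argmax(vals, axis=1)
        first = self.pair_codes[best] // self.n_structures
        empty = ~np.isfinite(vals[np.arange(vals.shape[0]), best])
        first = first.astype(np.int64)
        first[empty] = -1
        return first


@dataclass
class ParcellationResult:
    """Final labels plus the per-structure volume accounting."""

    labels: LabelVolume
    structure_ids: list[int]
    achieved_voxels: np.ndarray  # (S,) int64
    target_voxels: np.ndarray  # (S,) int64
    target_volumes_mm3: np.ndarray  # (S,) float64
    observed_volumes_mm3: np.ndarray  # (S,) float64
    n_iter: int
    trace: list[float]
    converged: bool
    posteriors: PosteriorMap | None = None
    corrected: np.ndarray | None = None  # (S, X, Y, Z)


def _sample_bins(values: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    width = (hi - lo) / n_bins
    bins = np.floor((values - lo) / width).astype(np.int64)
    clamped = int(((bins < 0) | (bins >= n_bins)).sum())
    if clamped:
        logger.info("%d intensities outside histogram range; clamped to edge bins", clamped)
    return np.clip(bins, 0, n_bins - 1)


def voxelwise_posteriors(atlas: Atlas, contrasts: list[ScalarVolume]) -> PosteriorMap:
    """Combine atlas priors with the subject's intensity likelihoods.

    For i != j the posterior is prior x likelihood; for i == i the spatial
    term is ``max(P(B_i|i), sqrt(P(S_i)))``. Likelihoods are sampled from the
    pair histograms, renormalized per contrast so that the 95th percentile of
    the per-voxel maxima equals 0.95, and fused across contrasts by geometric
    mean.
    """
    if len(contrasts) != len(atlas.contrast_names):
        raise ValueError("contrast count does not match the atlas")
    check_same_grid(atlas.grid, *[c.grid for c in contrasts])
    s = atlas.n_structures
    region_idx = np.flatnonzero(atlas.region.ravel())
    k = atlas.k
    pv = atlas.prior_values.reshape(-1, k)[region_idx]
    pc = atlas.prior_pairs.reshape(-1, k)[region_idx]
    kept_slots = pc >= 0

    codes = np.unique(pc[kept_slots]).astype(np.int64)
    code_pos = np.full(s * s, -1, dtype=np.int64)
    code_pos[codes] = np.arange(len(codes))

    n_v = len(region_idx)
    n_p = len(codes)
    prior = np.zeros((n_v, n_p), dtype=np.float64)
    kept = np.zeros((n_v, n_p), dtype=bool)
    rows = np.repeat(np.arange(n_v), k).reshape(n_v, k)
    cols = np.where(kept_slots, code_pos[np.where(kept_slots, pc, 0)], 0)
    prior[rows[kept_slots], cols[kept_slots]] = pv[kept_slots]
    kept[rows[kept_slots], cols[kept_slots]] = True

    # interior pairs compete with the square root of the skeleton prior
    skel = atlas.skeleton_priors.reshape(-1, s)[region_idx]
    for a in range(s):
        code = a * s + a
        p = code_pos[code]
        if p < 0:
            continue
        here = kept[:, p]
        prior[here, p] = np.maximum(prior[here, p], np.sqrt(skel[here, a]))

    # per-contrast histogram likelihoods, percentile-renormalized then fused
    n_c = len(contrasts)
    like = np.ones((n_v, n_p), dtype=np.float64)
    for c in range(n_c):
        lo, hi = atlas.hist_ranges[c]
        bins = _sample_bins(contrasts[c].values.ravel()[region_idx], lo, hi, atlas.n_bins)
        h_c = atlas.histograms[codes, c][:, bins].T  # (V, P)
        h_c[~kept] = 0.0
        vmax = h_c.max(axis=1)
        q = float(np.percentile(vmax, 95.0, method="linear"))
        if q <= 0:
            raise ValueError("intensity likelihoods vanish over the region")
        like *= h_c * (0.95 / q)
    like **= 1.0 / n_c

    values = prior * like
    values[~kept] = 0.0
    return PosteriorMap(
        shape=atlas.grid.shape,
        structure_ids=list(atlas.structure_ids),
        pair_codes=codes,
        region_idx=region_idx,
        values=values,
        kept=kept,
    )


def similarity_weight(
    r_x: np.ndarray, r_y: np.ndarray, sigmas: np.ndarray
) -> float | np.ndarray:
    """Intensity similarity ``prod_c exp(-(R_c(y) - R_c(x))^2 / 2 sigma_c^2)``.

    Symmetric, in (0, 1], equal to 1 for identical intensity vectors.
    """
    r_x = np.asarray(r_x, dtype=np.float64)
    r_y = np.asarray(r_y, dtype=np.float64)
    sigmas = np.asarray(sigmas, dtype=np.float64)
    if not (np.isfinite(r_x).all() and np.isfinite(r_y).all()):
        raise ValueError("non-finite intensities")
    if (sigmas <= 0).any():
        raise ValueError("similarity scales must be positive")
    d2 = ((r_y - r_x) ** 2 / (2.0 * sigmas**2)).sum(axis=0)
    return np.exp(-d2)


def contrast_similarity_scales(atlas: Atlas) -> np.ndarray:
    """Per-contrast sigma for the MRF: median of the histogram stds."""
    sig = []
    for c in range(len(atlas.contrast_names)):
        vals = atlas.hist_sigma[:, c]
        vals = vals[vals > 0]
        if len(vals) == 0:
            raise ValueError("no positive histogram scales for a contrast")
        sig.append(float(np.median(vals)))
    return np.array(sig)


def _neighborhood(
    pm: PosteriorMap, contrast_values: np.ndarray, sigmas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Select, once, each voxel's 4 most intensity-similar in-region
    26-neighbors. Returns (neighbor region-row indices (V, 4), weights
    (V, 4)); missing neighbors carry weight 0."""
    shape = pm.shape
    n_v = len(pm.region_idx)
    coords = np.stack(np.unravel_index(pm.region_idx, shape), axis=1)  # (V, 3)
    full_to_region = np.full(int(np.prod(shape)), -1, dtype=np.int64)
    full_to_region[pm.region_idx] = np.arange(n_v)

    r_here = contrast_values[:, coords[:, 0], coords[:, 1], coords[:, 2]]  # (C, V)
    sims = np.full((26, n_v), -1.0)
    nbr_rows = np.full((26, n_v), -1, dtype=np.int64)
    for kk, off in enumerate(_OFFSETS26):
        nc = coords + off
        ok = np.all((nc >= 0) & (nc < np.array(shape)), axis=1)
        flat = np.ravel_multi_index(
            (nc[ok, 0], nc[ok, 1], nc[ok, 2]), shape
        )
        rows = full_to_region[flat]
        in_region = rows >= 0
        sel = np.flatnonzero(ok)[in_region]
        rows = rows[in_region]
        r_nbr = contrast_values[:, nc[sel, 0], nc[sel, 1], nc[sel, 2]]
        d2 = ((r_nbr - r_here[:, sel]) ** 2 / (2.0 * sigmas[:, None] ** 2)).sum(axis=0)
        sims[kk, sel] = np.exp(-d2)
        nbr_rows[kk, sel] = rows

    top = np.argpartition(-sims, 3, axis=0)[:4]  # (4, V)
    top_sims = np.take_along_axis(sims, top, axis=0)
    # deterministic: sort the four by similarity desc, then offset index asc
    order = np.lexsort((top, -top_sims), axis=0)
    top = np.take_along_axis(top, order, axis=0)
    top_sims = np.take_along_axis(top_sims, order, axis=0)
    top_rows = np.take_along_axis(nbr_rows, top, axis=0)
    weights = np.where(top_rows >= 0, top_sims, 0.0)
    top_rows = np.where(top_rows >= 0, top_rows, 0)
    return top_rows.T.copy(), weights.T.copy()


def mrf_diffusion(
    pm: PosteriorMap,
    contrast_values: np.ndarray,
    sigmas: np.ndarray,
    stop_ratio: float = 0.001,
    max_iter: int = 200,
) -> PosteriorMap:
    """Diffuse pair posteriors over the fixed similarity neighborhood.

    Each kept pair probability is replaced by the similarity-weighted
    average over the voxel itself and its four most similar 26-neighbors
    (neighborhood selected once from the intensities and frozen). Iteration
    stops when the fraction of changed argmax labels over the region falls
    below ``stop_ratio``, or at ``max_iter`` (flagged as non-converged).
    """
    nbr_rows, weights = _neighborhood(pm, np.asarray(contrast_values, float), sigmas)
    wsum = 1.0 + weights.sum(axis=1)
    values = pm.values.copy()
    labels = pm.argmax_structure()
    trace: list[float] = []
    converged = False
    n_v = values.shape[0]
    it = 0
    for it in range(1, max_iter + 1):
        acc = values.copy()
        for n in range(nbr_rows.shape[1]):
            acc += weights[:, n : n + 1] * values[nbr_rows[:, n]]
        values = acc / wsum[:, None]
        values[~pm.kept] = 0.0
        new = PosteriorMap(
            pm.shape, pm.structure_ids, pm.pair_codes, pm.region_idx, values, pm.kept
        )
        new_labels = new.argmax_structure()
        ratio = float(np.count_nonzero(new_labels != labels)) / n_v
        trace.append(ratio)
        labels = new_labels
        if ratio < stop_ratio:
            converged = True
            break
    if not converged:
        logger.warning("diffusion did not converge within %d iterations", max_iter)
    return PosteriorMap(
        pm.shape,
        pm.structure_ids,
        pm.pair_codes,
        pm.region_idx,
        values,
        pm.kept,
        n_iter=it,
        trace=trace,
        converged=converged,
    )


def collapse_to_structures(pm: PosteriorMap) -> np.ndarray:
    """Per-structure posterior: max over that structure's kept pairs.

    Returns a (S, X, Y, Z) array (zero outside the region and for
    structures with no kept entry at a voxel).
    """
    s = pm.n_structures
    first = pm.pair_codes // s
    out = np.zeros((s,) + tuple(pm.shape), dtype=np.float64)
    vals = np.where(pm.kept, pm.values, 0.0)
    flat = out.reshape(s, -1)
    for a in range(s):
        cols = np.flatnonzero(first == a)
        if len(cols):
            flat[a, pm.region_idx] = vals[:, cols].max(axis=1)
    return out


def target_volume(v_obs: float, mu_logv: float, sigma_logv: float) -> float:
    """Blend observed and prior volume (mm^3) by log-normal plausibility.

    ``V_hat = P V + (1 - P) exp(mu)`` with ``P = exp(-(ln V - mu)^2 / (2
    sigma^2))``, an unnormalized log-Gaussian in [0, 1]: implausible observed
    volumes are pulled toward the prior mean, so structures always grow to a
    plausible size.
    """
    if v_obs <= 0:
        raise ValueError("observed volume must be positive")
    p = float(np.exp(-0.5 * (np.log(v_obs) - mu_logv) ** 2 / sigma_logv**2))
    return p * v_obs + (1.0 - p) * float(np.exp(mu_logv))


def parcellate(
    atlas: Atlas,
    contrasts: list[ScalarVolume],
    stop_ratio: float = 0.001,
    max_iter: int = 200,
    membership_threshold: float = 0.5,
    keep_intermediates: bool = False,
) -> ParcellationResult:
    """Full inference pipeline on one subject; deterministic."""
    pm = voxelwise_posteriors(atlas, contrasts)
    cvals = np.stack([c.values for c in contrasts])
    sigmas = contrast_similarity_scales(atlas)
    pm = mrf_diffusion(pm, cvals, sigmas, stop_ratio=stop_ratio, max_iter=max_iter)
    sp = collapse_to_structures(pm)

    s = atlas.n_structures
    corrected = np.zeros_like(sp)
    for a in range(s):
        corrected[a] = topology_correct_field(sp[a])

    voxvol = atlas.grid.voxel_volume
    amax = corrected.argmax(axis=0)
    vmax = corrected.max(axis=0)
    member = vmax >= membership_threshold
    observed = np.array(
        [float(np.count_nonzero(member & (amax == a))) * voxvol for a in range(s)]
    )
    targets = np.empty(s)
    for a in range(s):
        if observed[a] > 0:
            targets[a] = target_volume(observed[a], atlas.mu_logv[a], atlas.sigma_logv[a])
        else:
            targets[a] = float(np.exp(atlas.mu_logv[a]))
    budgets = np.round(targets / voxvol).astype(np.int64)
    seeds = np.array(
        [int(np.argmax(corrected[a].ravel())) for a in range(s)], dtype=np.int64
    )
    label_idx, counts = grow_regions(corrected, np.moveaxis(atlas.skeleton_priors, -1, 0), budgets, seeds)

    ids = np.array(atlas.structure_ids, dtype=np.int32)
    labels = np.zeros(atlas.grid.shape, dtype=np.int32)
    assigned = label_idx >= 0
    labels[assigned] = ids[label_idx[assigned]]
    lv = LabelVolume(atlas.grid, labels, dict(atlas.structure_names))
    return ParcellationResult(
        labels=lv,
        structure_ids=list(atlas.structure_ids),
        achieved_voxels=counts,
        target_voxels=budgets,
        target_volumes_mm3=targets,
        observed_volumes_mm3=observed,
        n_iter=pm.n_iter,
        trace=list(pm.trace),
        converged=pm.converged,
        posteriors=pm if keep_intermediates else None,
        corrected=corrected if keep_intermediates else None,
    )
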