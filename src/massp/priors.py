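"""Atlas construction: interface, skeleton, intensity and volume priors.

From N co-registered expert delineations (and their quantitative contrasts)
the builder derives:

* **Interface priors** — for every ordered structure pair (i, j), the signed
  distance ``d_i|j = max(phi_i, phi_j - delta)`` whose non-positive set is the
  band "inside i, within delta of j" (``d_i|i = phi_i`` marks the whole
  interior of i). Across subjects, each voxel gets a Gaussian plausibility
  ``(2 pi sigma^2)^(-1/2) exp(-mu^2 / 2 sigma^2)`` with ``mu`` the mean of
  the subject distances and ``sigma`` their population std plus delta (the
  partial-voluming scale). Only the K largest pair entries are kept per
  voxel, and one global factor rescales the map so that the 95th percentile
  of per-voxel maxima (over the sampling region) equals 0.95.
* **Skeleton priors** — the same Gaussian construction applied to the
  distance-to-skeleton fields, rescaled with the same interface factor.
* **Intensity priors** — 200-bin histograms per ordered pair and contrast,
  accumulated over subjects with weights combining the spatial prior and a
  robust group-consistency Gaussian.
* **Volume priors** — a log-normal model: mean and population std of the
  log structure volumes (mm^3).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .atlas import Atlas
from .geometry import signed_distance, skeletonize
from .grids import LabelVolume, ScalarVolume, check_same_grid

__all__ = [
    "interface_distance",
    "build_interface_priors",
    "build_skeleton_priors",
    "robust_stats",
    "build_intensity_histograms",
    "build_volume_priors",
    "build_atlas",
]

# IQR of the standard normal distribution; IQR / 1.349 is a consistent,
# outlier-robust estimator of the standard deviation.
_NORMAL_IQR = 1.349

_SIGMA_FLOOR = 1e-6


def interface_distance(
    phi_i: np.ndarray,
    phi_j: np.ndarray,
    delta: float = 1.0,
    same: bool = False,
    form: str = "band",
) -> np.ndarray:
    """Interface distance ``d_i|j`` from two structure SDFs (voxel units).

    ``form="band"`` (default): ``max(phi_i, phi_j - delta)`` for i != j, whose
    zero level set bounds exactly the band inside i within delta of j, and
    ``phi_i`` for i == j (the structure interior). ``form="printed"`` selects
    the alternative clamp ``min(phi_i, phi_j - delta, 0)`` for comparison; it
    is non-positive everywhere.
    """
    phi_i = np.asarray(phi_i, dtype=np.float64)
    phi_j = np.asarray(phi_j, dtype=np.float64)
    if phi_i.shape != phi_j.shape:
        raise ValueError("SDFs must share a grid")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if form == "band":
        if same:
            return phi_i.copy()
        return np.maximum(phi_i, phi_j - delta)
    if form == "printed":
        return np.minimum(np.minimum(phi_i, phi_j - delta), 0.0)
    raise ValueError(f"unknown interface form {form!r}")


def _gaussian_plausibility(stack: np.ndarray, delta: float) -> np.ndarray:
    """Eq.-style prior from a (N, ...) stack of per-subject distances."""
    mu = stack.mean(axis=0)
    sigma = stack.std(axis=0) + delta  # population std, + delta after the sqrt
    return np.exp(-0.5 * mu**2 / sigma**2) / np.sqrt(2.0 * np.pi * sigma**2)


def _check_cohort(delineations: list[LabelVolume]) -> tuple[list[int], object]:
    if len(delineations) < 2:
        raise ValueError("at least 2 delineated subjects are required")
    grid = check_same_grid(*[d.grid for d in delineations])
    ids = delineations[0].structure_ids
    for d in delineations[1:]:
        if d.structure_ids != ids:
            raise ValueError(
                "all subjects must contain the same structures; "
                f"{ids} vs {d.structure_ids}"
            )
    for d in delineations:
        for sid in ids:
            if not (d.labels == sid).any():
                raise ValueError(f"structure {sid} is empty in one subject")
    return ids, grid


def _subject_sdfs(delineations: list[LabelVolume], ids: list[int]) -> np.ndarray:
    """(N, S, X, Y, Z) stack of structure SDFs."""
    return np.stack(
        [
            np.stack([signed_distance(d.labels == sid) for sid in ids])
            for d in delineations
        ]
    )


def sampling_region(delineations: list[LabelVolume], radius_mm: float) -> np.ndarray:
    """Voxels within ``radius_mm`` of any delineated structure (any subject)."""
    union = np.zeros(delineations[0].grid.shape, dtype=bool)
    for d in delineations:
        union |= d.labels > 0
    dist = ndimage.distance_transform_edt(
        ~union, sampling=delineations[0].grid.voxel_size
    )
    return dist <= radius_mm


def dense_interface_priors(
    phis: np.ndarray, delta: float, form: str = "band"
) -> np.ndarray:
    """All-pairs interface priors, densely: (X, Y, Z, S*S) float64.

    ``phis`` is the (N, S, X, Y, Z) stack of subject SDFs. Pair (a, b) lives
    at index ``a * S + b``.
    """
    n, s = phis.shape[:2]
    shape = phis.shape[2:]
    dense = np.empty(shape + (s * s,), dtype=np.float64)
    for a in range(s):
        for b in range(s):
            d = interface_distance(
                phis[:, a], phis[:, b], delta=delta, same=(a == b), form=form
            )
            dense[..., a * s + b] = _gaussian_plausibility(d, delta)
    return dense


def sparsify_top_k(dense: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep the K largest pair entries per voxel, sorted descending.

    Ties are broken by ascending pair code; slots holding exactly zero are
    marked empty (pair code -1).
    """
    shape, n_pairs = dense.shape[:-1], dense.shape[-1]
    flat = dense.reshape(-1, n_pairs)
    kk = min(k, n_pairs)
    if kk < n_pairs:
        part = np.argpartition(-flat, kk - 1, axis=1)[:, :kk]
        vals = np.take_along_axis(flat, part, axis=1)
    else:
        part = np.broadcast_to(np.arange(n_pairs), flat.shape).copy()
        vals = flat.copy()
    # make tie order deterministic: sort candidate codes ascending first
    code_order = np.argsort(part, axis=1, kind="stable")
    part = np.take_along_axis(part, code_order, axis=1)
    vals = np.take_along_axis(vals, code_order, axis=1)
    order = np.argsort(-vals, axis=1, kind="stable")
    vals = np.take_along_axis(vals, order, axis=1)
    codes = np.take_along_axis(part, order, axis=1).astype(np.int32)
    codes[vals <= 0.0] = -1
    out_vals = np.zeros(flat.shape[0] * k, dtype=np.float64).reshape(-1, k)
    out_codes = np.full((flat.shape[0], k), -1, dtype=np.int32)
    out_vals[:, :kk] = vals
    out_codes[:, :kk] = codes
    return out_vals.reshape(shape + (k,)), out_codes.reshape(shape + (k,))


def rescale_factor(per_voxel_max: np.ndarray, target: float = 0.95) -> float:
    """Factor mapping the 95th percentile of per-voxel maxima to ``target``."""
    q = float(np.percentile(per_voxel_max, 95.0, method="linear"))
    if q <= 0:
        raise ValueError("cannot rescale: 95th percentile of maxima is zero")
    return target / q


def build_interface_priors(
    delineations: list[LabelVolume],
    delta: float = 1.0,
    k: int = 16,
    radius_mm: float = 10.0,
    form: str = "band",
    phis: np.ndarray | None = None,
    region: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sparse top-K interface prior map from N delineations.

    Returns ``(values, pair_codes, scale_factor)``; values are already
    multiplied by the global factor that anchors the 95th percentile of the
    per-voxel maxima (over the sampling region) at 0.95.
    """
    ids, _ = _check_cohort(delineations)
    if phis is None:
        phis = _subject_sdfs(delineations, ids)
    if region is None:
        region = sampling_region(delineations, radius_mm)
    dense = dense_interface_priors(phis, delta, form=form)
    vals, codes = sparsify_top_k(dense, k)
    factor = rescale_factor(vals[..., 0][region])
    vals *= factor
    return vals, codes, factor


def build_skeleton_priors(
    delineations: list[LabelVolume],
    delta: float = 1.0,
    scale_factor: float = 1.0,
    interface_values: np.ndarray | None = None,
    interface_codes: np.ndarray | None = None,
    clip: bool = True,
    phis: np.ndarray | None = None,
) -> np.ndarray:
    """Per-structure skeleton prior fields (X, Y, Z, S).

    Each structure's prior follows the same Gaussian pattern as the interface
    priors, applied to the subject distance-to-skeleton fields, and is
    rescaled with the interface factor. With ``clip=True`` the stored field
    is additionally bounded by the kept interior prior P(B_i|i) at every
    voxel (skeletons lie inside their structure).
    """
    ids, grid = _check_cohort(delineations)
    s = len(ids)
    if phis is None:
        phis = _subject_sdfs(delineations, ids)
    out = np.empty(grid.shape + (s,), dtype=np.float64)
    for a in range(s):
        sk = np.stack([skeletonize(phis[n, a])[1] for n in range(phis.shape[0])])
        p = _gaussian_plausibility(sk, delta) * scale_factor
        out[..., a] = p
    if clip:
        if interface_values is None or interface_codes is None:
            raise ValueError("clipping requires the kept interface prior map")
        for a in range(s):
            code = a * s + a
            hit = interface_codes == code
            b_ii = np.where(hit, interface_values, 0.0).sum(axis=-1)
            out[..., a] = np.minimum(out[..., a], b_ii)
    return out


def robust_stats(values: np.ndarray, axis: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Outlier-robust location and scale of a sample.

    Location is the median; scale is IQR / 1.349 (quantiles by linear
    interpolation), which estimates the standard deviation consistently for
    Gaussian data. The scale is floored at a small positive value so that
    downstream Gaussian weights never divide by zero.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.shape[axis] if axis is not None else values.size
    if n < 2:
        raise ValueError("robust statistics need at least 2 values")
    if not np.isfinite(values).all():
        raise ValueError("robust statistics require finite values")
    loc = np.median(values, axis=axis)
    q75, q25 = np.percentile(values, [75.0, 25.0], axis=axis, method="linear")
    scale = (q75 - q25) / _NORMAL_IQR
    scale = np.maximum(scale, _SIGMA_FLOOR)
    return loc, scale


def build_intensity_histograms(
    contrasts: list[list[ScalarVolume]],
    phis: np.ndarray,
    region: np.ndarray,
    delta: float = 1.0,
    n_bins: int = 200,
    form: str = "band",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interface intensity histograms from N subjects' contrast volumes.

    ``contrasts[n][c]`` is contrast c of subject n; ``phis`` is the
    (N, S, X, Y, Z) stack of subject SDFs. Per contrast, 200 equal-width
    bins cover the global intensity range over the sampling region. For each
    ordered pair (i, j), a voxel of subject n contributes when it lies in
    that subject's own interface band (``d_i|j,n(x) <= 0`` — inside i,
    within delta of j; the whole interior of i for i == i), with the weight
    ``N(R_n(x); mu_R(x), sigma_R(x))`` measuring the consistency of the
    subject's intensity with the group (mu_R/sigma_R are the robust median
    and IQR/1.349 across subjects at x). Histograms are normalized to unit
    maximum; the weighted standard deviation of each is recorded.

    Returns ``(histograms (S*S, C, B), ranges (C, 2), sigmas (S*S, C))``.
    """
    n_subj = len(contrasts)
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if phis.shape[0] != n_subj:
        raise ValueError("one SDF stack per subject is required")
    n_structures = phis.shape[1]
    n_contrast = len(contrasts[0])
    for subj in contrasts:
        if len(subj) != n_contrast:
            raise ValueError("all subjects must supply all contrasts")
    if not region.any():
        raise ValueError("sampling region is empty")

    ridx = np.flatnonzero(region.ravel())
    n_pairs = n_structures * n_structures

    # (C, N, V) region-restricted intensities
    intens = np.stack(
        [
            np.stack([contrasts[n][c].values.ravel()[ridx] for n in range(n_subj)])
            for c in range(n_contrast)
        ]
    )
    ranges = np.array(
        [[intens[c].min(), intens[c].max()] for c in range(n_contrast)],
        dtype=np.float64,
    )
    hist = np.zeros((n_pairs, n_contrast, n_bins), dtype=np.float64)

    # per-contrast group-consistency weights and bin indices
    gweights = np.empty_like(intens)
    bindex = np.empty(intens.shape, dtype=np.int64)
    for c in range(n_contrast):
        lo, hi = ranges[c]
        if hi <= lo:
            raise ValueError(f"contrast {c} has zero intensity range over the region")
        mu, sigma = robust_stats(intens[c], axis=0)
        width = (hi - lo) / n_bins
        for n in range(n_subj):
            r = intens[c, n]
            gweights[c, n] = np.exp(-0.5 * ((r - mu) / sigma) ** 2) / (
                np.sqrt(2 * np.pi) * sigma
            )
            bindex[c, n] = np.clip(((r - lo) / width).astype(np.int64), 0, n_bins - 1)

    phi_region = phis.reshape(n_subj, n_structures, -1)[:, :, ridx]
    for a in range(n_structures):
        for b in range(n_structures):
            code = a * n_structures + b
            for n in range(n_subj):
                d = interface_distance(
                    phi_region[n, a], phi_region[n, b], delta=delta,
                    same=(a == b), form=form,
                )
                sel = np.flatnonzero(d <= 0.0)
                if sel.size == 0:
                    continue
                for c in range(n_contrast):
                    hist[code, c, :] += np.bincount(
                        bindex[c, n, sel],
                        weights=gweights[c, n, sel],
                        minlength=n_bins,
                    )

    centers = ranges[:, 0, None] + (np.arange(n_bins) + 0.5) * (
        (ranges[:, 1] - ranges[:, 0]) / n_bins
    )[:, None]
    sigmas = np.zeros((n_pairs, n_contrast))
    for c in range(n_contrast):
        mass = hist[:, c, :].sum(axis=1)
        ok = mass > 0
        m1 = (hist[:, c, :] * centers[c]) @ np.ones(n_bins)
        mean = np.where(ok, m1 / np.where(ok, mass, 1.0), 0.0)
        var = (hist[:, c, :] * (centers[c][None, :] - mean[:, None]) ** 2).sum(
            axis=1
        ) / np.where(ok, mass, 1.0)
        sigmas[:, c] = np.where(ok, np.sqrt(var), 0.0)
        peak = hist[:, c, :].max(axis=1)
        hist[ok, c, :] /= peak[ok, None]
    return hist, ranges, sigmas


def fused_likelihood(histograms: np.ndarray, bin_indices: np.ndarray) -> np.ndarray:
    """Geometric-mean fusion of per-contrast histogram values.

    ``histograms`` is (C, B) for one pair; ``bin_indices`` is (C, ...) of bin
    positions. Returns ``(prod_c H_c)^(1/C)``.
    """
    n_c = histograms.shape[0]
    prod = np.ones(bin_indices.shape[1:], dtype=np.float64)
    for c in range(n_c):
        prod *= histograms[c][bin_indices[c]]
    return prod ** (1.0 / n_c)


def build_volume_priors(
    delineations: list[LabelVolume],
) -> tuple[np.ndarray, np.ndarray]:
    """Log-normal volume priors: mean and population std of log V (mm^3)."""
    ids, grid = _check_cohort(delineations)
    logv = np.empty((len(delineations), len(ids)))
    for n, d in enumerate(delineations):
        for a, sid in enumerate(ids):
            v = d.volume_mm3(sid)
            if v <= 0:
                raise ValueError(f"structure {sid} has zero volume in subject {n}")
            logv[n, a] = np.log(v)
    mu = logv.mean(axis=0)
    sigma = np.maximum(logv.std(axis=0), _SIGMA_FLOOR)
    return mu, sigma


def build_atlas(
    delineations: list[LabelVolume],
    contrasts: list[list[ScalarVolume]],
    contrast_names: list[str] | None = None,
    delta: float = 1.0,
    k: int = 16,
    n_bins: int = 200,
    radius_mm: float = 10.0,
    interface_form: str = "band",
    clip_skeleton: bool = True,
) -> Atlas:
    """Construct the full atlas from N delineated, contrast-imaged subjects."""
    ids, grid = _check_cohort(delineations)
    if len(contrasts) != len(delineations):
        raise ValueError("one contrast set per delineated subject is required")
    n_contrast = len(contrasts[0])
    check_same_grid(grid, *[c.grid for subj in contrasts for c in subj])
    if contrast_names is None:
        contrast_names = [f"contrast_{c}" for c in range(n_contrast)]

    phis = _subject_sdfs(delineations, ids)
    region = sampling_region(delineations, radius_mm)
    vals, codes, factor = build_interface_priors(
        delineations, delta=delta, k=k, radius_mm=radius_mm, form=interface_form,
        phis=phis, region=region,
    )
    skel = build_skeleton_priors(
        delineations, delta=delta, scale_factor=factor,
        interface_values=vals, interface_codes=codes, clip=clip_skeleton, phis=phis,
    )
    hist, ranges, sigmas = build_intensity_histograms(
        contrasts, phis, region, delta=delta, n_bins=n_bins, form=interface_form
    )
    mu_logv, sigma_logv = build_volume_priors(delineations)
    atlas = Atlas(
        grid=grid,
        structure_ids=ids,
        structure_names=dict(delineations[0].label_table),
        delta=delta,
        k=k,
        n_bins=n_bins,
        radius_mm=radius_mm,
        contrast_names=list(contrast_names),
        n_subjects=len(delineations),
        scale_factor=factor,
        prior_values=vals,
        prior_pairs=codes,
        skeleton_priors=skel,
        region=region,
        histograms=hist,
        hist_ranges=ranges,
        hist_sigma=sigmas,
        mu_logv=mu_logv,
        sigma_logv=sigma_logv,
        skeleton_clipped=clip_skeleton,
    )
    atlas.validate()
    return atlas
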