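"""Remapping atlas intensity histograms onto new, non-quantitative contrasts.

Given a co-aligned reference image in the atlas' quantitative channels and
the same anatomy imaged in new channels (e.g. T1w/T2w), each pair's new
histogram accumulates, per new-intensity bin, the spatial prior weighted by
the joint likelihood of the reference intensities under the source
histograms. The spatial and volume priors are untouched; only the intensity
model and contrast names are swapped.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .atlas import Atlas
from .grids import ScalarVolume, check_same_grid

__all__ = ["remap_histograms"]


def remap_histograms(
    atlas: Atlas,
    reference_quant: list[ScalarVolume],
    new_contrasts: list[ScalarVolume],
    new_names: list[str] | None = None,
    geometric_mean: bool = False,
) -> Atlas:
    """Project the joint source-contrast likelihood onto new contrasts.

    For each new contrast and ordered pair (i, j), bin b accumulates the sum
    over voxels whose new intensity falls in b of ``P(x in B_i|j) * prod_c
    H_i|j,c(ref_c(x))`` — the plain product of the source histogram
    likelihoods (``geometric_mean=True`` applies the 1/C exponent instead,
    for sensitivity checks). A pair whose remapped histogram is identically
    zero on every new contrast (prior support does not intersect the image)
    is rejected.
    """
    if len(reference_quant) != len(atlas.contrast_names):
        raise ValueError("reference volumes must match the atlas contrasts")
    if not new_contrasts:
        raise ValueError("no new contrasts given")
    check_same_grid(
        atlas.grid,
        *[v.grid for v in reference_quant],
        *[v.grid for v in new_contrasts],
    )
    if new_names is None:
        new_names = [f"new_contrast_{c}" for c in range(len(new_contrasts))]
    if len(new_names) != len(new_contrasts):
        raise ValueError("one name per new contrast is required")

    s = atlas.n_structures
    k = atlas.k
    n_bins = atlas.n_bins
    region_idx = np.flatnonzero(atlas.region.ravel())
    pv = atlas.prior_values.reshape(-1, k)[region_idx]
    pc = atlas.prior_pairs.reshape(-1, k)[region_idx]
    kept = pc >= 0

    # joint source likelihood of the reference intensities, per kept slot
    joint = np.ones_like(pv)
    n_src = len(reference_quant)
    for c in range(n_src):
        lo, hi = atlas.hist_ranges[c]
        width = (hi - lo) / n_bins
        bins = np.clip(
            ((reference_quant[c].values.ravel()[region_idx] - lo) / width).astype(np.int64),
            0,
            n_bins - 1,
        )
        h = atlas.histograms[:, c, :]  # (S*S, B)
        joint *= h[np.where(kept, pc, 0), bins[:, None]]
    if geometric_mean:
        joint **= 1.0 / n_src
    weights = pv * joint * kept

    n_new = len(new_contrasts)
    new_hist = np.zeros((s * s, n_new, n_bins), dtype=np.float64)
    new_ranges = np.zeros((n_new, 2), dtype=np.float64)
    codes = np.where(kept, pc, 0).astype(np.int64)
    for c in range(n_new):
        vals = new_contrasts[c].values.ravel()[region_idx]
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            raise ValueError(f"new contrast {c} has zero intensity range")
        new_ranges[c] = (lo, hi)
        width = (hi - lo) / n_bins
        bins = np.clip(((vals - lo) / width).astype(np.int64), 0, n_bins - 1)
        keys = codes * n_bins + bins[:, None]
        new_hist[:, c, :] = np.bincount(
            keys.ravel(), weights=weights.ravel(), minlength=s * s * n_bins
        ).reshape(s * s, n_bins)

    # only pairs that had an intensity model can lose it in the remap;
    # pairs with empty source histograms (never-adjacent structures) stay zero
    kept_codes = np.unique(codes[kept])
    modeled = [int(p) for p in kept_codes if atlas.histograms[p].any()]
    dead = [int(p) for p in modeled if not new_hist[p].any()]
    if dead:
        raise ValueError(
            f"remapped histograms are identically zero for pair codes {dead}; "
            "prior support does not intersect the image"
        )

    # summary std and unit-maximum normalization, as in atlas construction
    centers = new_ranges[:, 0, None] + (np.arange(n_bins) + 0.5) * (
        (new_ranges[:, 1] - new_ranges[:, 0]) / n_bins
    )[:, None]
    sigmas = np.zeros((s * s, n_new))
    for c in range(n_new):
        mass = new_hist[:, c, :].sum(axis=1)
        ok = mass > 0
        mean = np.where(ok, (new_hist[:, c, :] * centers[c]).sum(axis=1) / np.where(ok, mass, 1.0), 0.0)
        var = (new_hist[:, c, :] * (centers[c][None, :] - mean[:, None]) ** 2).sum(axis=1)
        sigmas[:, c] = np.where(ok, np.sqrt(var / np.where(ok, mass, 1.0)), 0.0)
        peak = new_hist[:, c, :].max(axis=1)
        new_hist[ok, c, :] /= peak[ok, None]

    return dataclasses.replace(
        atlas,
        contrast_names=list(new_names),
        histograms=new_hist,
        hist_ranges=new_ranges,
        hist_sigma=sigmas,
    )
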