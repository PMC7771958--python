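"""The atlas container: the four prior families plus metadata, and its
directory serialization.

The atlas is written as a directory rather than a single blob so every prior
is independently inspectable: NIfTI volumes for the spatial priors, TSV
tables for the histograms and volume priors, and a JSON manifest tying them
together. Reals round-trip bit-exactly (float64 NIfTI, %.17g text).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import VolumeGrid

__all__ = ["Atlas", "write_atlas", "read_atlas"]

_FMT = "%.17g"


@dataclass
class Atlas:
    """Aggregate of interface, skeleton, intensity and volume priors.

    Structures are indexed by their position in ``structure_ids`` (sorted
    label values); an ordered pair (i, j) — "inside i next to j" — is encoded
    as ``i_idx * n_structures + j_idx``.
    """

    grid: VolumeGrid
    structure_ids: list[int]
    structure_names: dict[int, str]
    delta: float
    k: int
    n_bins: int
    radius_mm: float
    contrast_names: list[str]
    n_subjects: int
    scale_factor: float
    # sparse interface prior: top-K entries per voxel
    prior_values: np.ndarray  # (X, Y, Z, K) float64
    prior_pairs: np.ndarray  # (X, Y, Z, K) int32, -1 = empty slot
    # per-structure skeleton prior fields (scaled with the interface factor)
    skeleton_priors: np.ndarray  # (X, Y, Z, S) float64
    # sampling region: within radius_mm of any delineated structure
    region: np.ndarray  # (X, Y, Z) bool
    # interface intensity histograms
    histograms: np.ndarray  # (S*S, C, n_bins) float64, unit maximum
    hist_ranges: np.ndarray  # (C, 2) float64 [min, max] per contrast
    hist_sigma: np.ndarray  # (S*S, C) float64 weighted std per histogram
    # log-normal volume priors (log mm^3)
    mu_logv: np.ndarray  # (S,) float64
    sigma_logv: np.ndarray  # (S,) float64
    skeleton_clipped: bool = True

    @property
    def n_structures(self) -> int:
        return len(self.structure_ids)

    def structure_index(self, structure_id: int) -> int:
        return self.structure_ids.index(structure_id)

    def pair_code(self, i_idx: int, j_idx: int) -> int:
        return i_idx * self.n_structures + j_idx

    def pair_indices(self, code: int) -> tuple[int, int]:
        return code // self.n_structures, code % self.n_structures

    def validate(self) -> None:
        """Check completeness: every structure in all four prior families."""
        s = self.n_structures
        if s == 0:
            raise ValueError("atlas has no structures")
        shp = self.grid.shape
        if self.prior_values.shape != shp + (self.k,):
            raise ValueError("interface prior values have wrong shape")
        if self.prior_pairs.shape != shp + (self.k,):
            raise ValueError("interface prior pair codes have wrong shape")
        if self.skeleton_priors.shape != shp + (s,):
            raise ValueError("skeleton prior fields have wrong shape")
        if self.histograms.shape != (s * s, len(self.contrast_names), self.n_bins):
            raise ValueError("histogram table has wrong shape")
        if self.mu_logv.shape != (s,) or self.sigma_logv.shape != (s,):
            raise ValueError("volume prior table has wrong shape")
        kept = self.prior_pairs[self.prior_pairs >= 0]
        present = np.unique(kept // s)
        if len(present) != s:
            raise ValueError("some structure has no kept interface prior entry")


def _save_nii(data: np.ndarray, grid: VolumeGrid, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    img.header.set_zooms(grid.voxel_size + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def _load_nii(path: Path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj)


def write_atlas(atlas: Atlas, path: str | Path) -> Path:
    """Serialize the atlas to a directory; returns the manifest path."""
    atlas.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _save_nii(atlas.prior_values.astype(np.float64), atlas.grid, path / "interface_prior_values.nii.gz")
    _save_nii(atlas.prior_pairs.astype(np.int32), atlas.grid, path / "interface_prior_pairs.nii.gz")
    _save_nii(atlas.skeleton_priors.astype(np.float64), atlas.grid, path / "skeleton_priors.nii.gz")
    _save_nii(atlas.region.astype(np.uint8), atlas.grid, path / "region.nii.gz")

    s = atlas.n_structures
    with open(path / "histograms.tsv", "w") as f:
        cols = "\t".join(f"b{b:03d}" for b in range(atlas.n_bins))
        f.write(f"label_i\tlabel_j\tcontrast\tsigma\t{cols}\n")
        for code in range(s * s):
            a, b = atlas.pair_indices(code)
            for c, cname in enumerate(atlas.contrast_names):
                vals = "\t".join(_FMT % v for v in atlas.histograms[code, c])
                f.write(
                    f"{atlas.structure_ids[a]}\t{atlas.structure_ids[b]}\t{cname}\t"
                    + (_FMT % atlas.hist_sigma[code, c])
                    + f"\t{vals}\n"
                )
    with open(path / "hist_ranges.tsv", "w") as f:
        f.write("contrast\tmin\tmax\n")
        for c, cname in enumerate(atlas.contrast_names):
            f.write(f"{cname}\t" + (_FMT % atlas.hist_ranges[c, 0]) + "\t" + (_FMT % atlas.hist_ranges[c, 1]) + "\n")
    with open(path / "volume_priors.tsv", "w") as f:
        f.write("structure_id\tname\tmu_log_mm3\tsigma_log_mm3\n")
        for idx, sid in enumerate(atlas.structure_ids):
            f.write(
                f"{sid}\t{atlas.structure_names[sid]}\t"
                + (_FMT % atlas.mu_logv[idx])
                + "\t"
                + (_FMT % atlas.sigma_logv[idx])
                + "\n"
            )

    manifest = {
        "format": "massp-atlas-1",
        "shape": list(atlas.grid.shape),
        "voxel_size": list(atlas.grid.voxel_size),
        "affine": [[float(v) for v in row] for row in atlas.grid.affine],
        "delta": atlas.delta,
        "k": atlas.k,
        "n_bins": atlas.n_bins,
        "radius_mm": atlas.radius_mm,
        "n_subjects": atlas.n_subjects,
        "scale_factor": atlas.scale_factor,
        "skeleton_clipped": atlas.skeleton_clipped,
        "contrasts": list(atlas.contrast_names),
        "structures": [
            {"id": sid, "name": atlas.structure_names[sid]} for sid in atlas.structure_ids
        ],
        "files": {
            "prior_values": "interface_prior_values.nii.gz",
            "prior_pairs": "interface_prior_pairs.nii.gz",
            "skeleton_priors": "skeleton_priors.nii.gz",
            "region": "region.nii.gz",
            "histograms": "histograms.tsv",
            "hist_ranges": "hist_ranges.tsv",
            "volume_priors": "volume_priors.tsv",
        },
    }
    mpath = path / "manifest.json"
    with open(mpath, "w") as f:
        json.dump(manifest, f, indent=1)
    return mpath


def read_atlas(path: str | Path) -> Atlas:
    """Read an atlas directory; verifies the manifest against the contents."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json under {path}")
    with open(mpath) as f:
        m = json.load(f)
    if m.get("format") != "massp-atlas-1":
        raise ValueError("unrecognized atlas manifest format")
    for fname in m["files"].values():
        if not (path / fname).exists():
            raise ValueError(f"manifest lists {fname} but it is missing")
    grid = VolumeGrid(tuple(m["shape"]), tuple(m["voxel_size"]), np.array(m["affine"]))
    structure_ids = [int(s["id"]) for s in m["structures"]]
    structure_names = {int(s["id"]): s["name"] for s in m["structures"]}
    n_s = len(structure_ids)
    n_c = len(m["contrasts"])
    n_bins = int(m["n_bins"])

    prior_values = _load_nii(path / m["files"]["prior_values"]).astype(np.float64)
    prior_pairs = _load_nii(path / m["files"]["prior_pairs"]).astype(np.int32)
    skeleton_priors = _load_nii(path / m["files"]["skeleton_priors"]).astype(np.float64)
    region = _load_nii(path / m["files"]["region"]).astype(bool)

    hist = np.zeros((n_s * n_s, n_c, n_bins))
    hist_sigma = np.zeros((n_s * n_s, n_c))
    cidx = {c: i for i, c in enumerate(m["contrasts"])}
    sidx = {sid: i for i, sid in enumerate(structure_ids)}
    n_rows = 0
    with open(path / m["files"]["histograms"]) as f:
        header = f.readline()
        if not header.startswith("label_i"):
            raise ValueError("malformed histogram table")
        for line in f:
            parts = line.rstrip("\n").split("\t")
            li, lj, cname = int(parts[0]), int(parts[1]), parts[2]
            if cname not in cidx:
                raise ValueError(f"histogram table lists unknown contrast {cname!r}")
            code = sidx[li] * n_s + sidx[lj]
            hist_sigma[code, cidx[cname]] = float(parts[3])
            hist[code, cidx[cname]] = [float(v) for v in parts[4:]]
            n_rows += 1
    if n_rows != n_s * n_s * n_c:
        raise ValueError(
            f"histogram table incomplete: {n_rows} rows, expected {n_s * n_s * n_c}"
        )

    hist_ranges = np.zeros((n_c, 2))
    with open(path / m["files"]["hist_ranges"]) as f:
        f.readline()
        for line in f:
            cname, lo, hi = line.rstrip("\n").split("\t")
            hist_ranges[cidx[cname]] = [float(lo), float(hi)]

    mu_logv = np.zeros(n_s)
    sigma_logv = np.zeros(n_s)
    seen = set()
    with open(path / m["files"]["volume_priors"]) as f:
        f.readline()
        for line in f:
            sid, _name, mu, sg = line.rstrip("\n").split("\t")
            mu_logv[sidx[int(sid)]] = float(mu)
            sigma_logv[sidx[int(sid)]] = float(sg)
            seen.add(int(sid))
    if seen != set(structure_ids):
        raise ValueError("volume prior table does not cover all structures")

    atlas = Atlas(
        grid=grid,
        structure_ids=structure_ids,
        structure_names=structure_names,
        delta=float(m["delta"]),
        k=int(m["k"]),
        n_bins=n_bins,
        radius_mm=float(m["radius_mm"]),
        contrast_names=list(m["contrasts"]),
        n_subjects=int(m["n_subjects"]),
        scale_factor=float(m["scale_factor"]),
        prior_values=prior_values,
        prior_pairs=prior_pairs,
        skeleton_priors=skeleton_priors,
        region=region,
        histograms=hist,
        hist_ranges=hist_ranges,
        hist_sigma=hist_sigma,
        mu_logv=mu_logv,
        sigma_logv=sigma_logv,
        skeleton_clipped=bool(m.get("skeleton_clipped", True)),
    )
    atlas.validate()
    return atlas
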