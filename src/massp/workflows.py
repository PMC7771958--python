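"""Experiment orchestration: run configuration, leave-one-out validation,
and provenance capture."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .estimator import MasspParcellator
from .inference import ParcellationResult
from .metrics import OverlapEntry, overlap_report
from .phantom import PhantomSubject

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "FoldResult", "leave_one_out", "provenance_record"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline knobs in one reproducible record.

    Defaults are the standard operating point: interface scale delta of one
    voxel, 16 kept prior entries, 200 histogram bins, a 10 mm sampling
    radius, and a 0.1% changed-label stopping ratio for the diffusion.
    """

    delta: float = 1.0
    k: int = 16
    n_bins: int = 200
    radius_mm: float = 10.0
    stop_ratio: float = 0.001
    max_iter: int = 200
    membership_threshold: float = 0.5
    interface_form: str = "band"
    clip_skeleton: bool = True
    seed: int = 42

    def estimator(self) -> MasspParcellator:
        params = dataclasses.asdict(self)
        params.pop("seed")
        return MasspParcellator(**params)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read ``key = value`` lines (TOML-style) into a config."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip().strip('"').strip("'")
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cls, key)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class FoldResult:
    held_out: int
    report: list[OverlapEntry]
    result: ParcellationResult | None
    error: str | None = None


def leave_one_out(
    cohort: list[PhantomSubject],
    config: RunConfig | None = None,
    keep_results: bool = False,
) -> list[FoldResult]:
    """For each subject: atlas from the others, parcellate, evaluate.

    A failing fold is recorded with its error and does not abort the rest.
    """
    if len(cohort) < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    config = config or RunConfig()
    folds: list[FoldResult] = []
    for i, test in enumerate(cohort):
        try:
            train = [s for j, s in enumerate(cohort) if j != i]
            est = config.estimator().fit(
                [s.contrasts for s in train], [s.truth for s in train]
            )
            result = est.predict_result(test.contrasts)
            report = overlap_report(result.labels, test.truth)
            folds.append(
                FoldResult(i, report, result if keep_results else None)
            )
        except Exception as exc:  # noqa: BLE001 - a fold must not kill the run
            logger.exception("fold %d failed", i)
            folds.append(FoldResult(i, [], None, error=str(exc)))
    return folds


def summarize_folds(folds: list[FoldResult]) -> dict[int, dict[str, float]]:
    """Per-structure means of dice / dilated dice / asd over valid folds."""
    acc: dict[int, dict[str, list[float]]] = {}
    for fold in folds:
        for e in fold.report:
            if not e.defined:
                continue
            d = acc.setdefault(e.structure_id, {"dice": [], "dilated_dice": [], "asd_voxels": []})
            d["dice"].append(e.dice)
            d["dilated_dice"].append(e.dilated_dice)
            if np.isfinite(e.asd_voxels):
                d["asd_voxels"].append(e.asd_voxels)
    return {
        sid: {k: float(np.mean(v)) for k, v in vals.items() if v}
        for sid, vals in acc.items()
    }


def provenance_record(config: RunConfig, extra: dict | None = None) -> dict:
    """Everything needed to reproduce a run bit-identically."""
    import massp

    rec = {
        "config": dataclasses.asdict(config),
        "versions": {
            "massp": massp.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    if extra:
        rec.update(extra)
    return rec


def write_provenance(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    Path(path).write_text(json.dumps(provenance_record(config, extra), indent=1))
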