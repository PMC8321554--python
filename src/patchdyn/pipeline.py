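"""End-to-end orchestration: preprocess → track → stats → CoV, with provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import Mask, Movie, RunConfig, read_movie, write_tracks
from .cov import cov_summary
from .metrics import PatchStats, compute_patch_stats
from .preprocess import make_presynaptic_mask, register_translation, subtract_movie_background
from .tracking import track_movie

logger = logging.getLogger("patchdyn")


@dataclass
class RunManifest:
    config: dict
    inputs: dict
    outputs: dict
    software_version: str
    rng_seed: int

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(
    config: RunConfig,
    movie: Movie | str | Path,
    out_dir: str | Path,
    mask: Mask | None = None,
) -> RunManifest:
    """Run preprocess → track → stats → CoV and write all outputs.

    ``movie`` may be a path (read with the config's calibration) or an
    in-memory :class:`Movie`.  Outputs: ``tracks.csv`` (+ summary),
    ``report.json`` (rejection counts), ``stats.json``, ``cov.json`` and
    ``manifest.json`` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs: dict = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise StageError(name, exc) from exc

    if not isinstance(movie, Movie):
        inputs["movie_path"] = str(movie)
        inputs["movie_sha256"] = _sha256(movie)
        movie = stage(
            "read", lambda: read_movie(movie, config.pixel_size_um, config.frame_interval_s)
        )

    pp = config.preprocess
    if pp.register:
        movie = stage("register", lambda: register_translation(movie, pp.max_shift_px).movie)
    if pp.subtract_background:
        movie = stage(
            "background", lambda: subtract_movie_background(movie, pp.rolling_ball_radius_px)
        )
    if mask is None:
        mask = stage(
            "mask",
            lambda: make_presynaptic_mask(
                movie, pp.mask_blur_sigma_px, pp.mask_method, pp.mask_keep_largest
            ),
        )

    accepted, report, _ = stage(
        "track", lambda: track_movie(movie, mask, config.detection, config.tracking)
    )
    stats = stage("stats", lambda: compute_patch_stats(accepted, mask, movie))
    cov = stage("cov", lambda: cov_summary(movie, mask, config.cov.n_bins))

    tracks_path = out_dir / "tracks.csv"
    write_tracks(accepted, tracks_path, movie.frame_interval_s)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(
            {"accepted": len(accepted), "rejected": report.counts},
            fh,
            indent=2,
        )
    with open(out_dir / "stats.json", "w") as fh:
        json.dump(stats.to_dict(), fh, indent=2)
    with open(out_dir / "cov.json", "w") as fh:
        json.dump(cov, fh, indent=2)

    manifest = RunManifest(
        config=config.to_dict(),
        inputs=inputs,
        outputs={
            "tracks": str(tracks_path),
            "report": str(out_dir / "report.json"),
            "stats": str(out_dir / "stats.json"),
            "cov": str(out_dir / "cov.json"),
        },
        software_version=__version__,
        rng_seed=config.rng_seed,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

COMPARE_COLUMNS = ["group", "movie", "frequency_per10um2_min", "mean_duration_s", "mean_rel_amplitude"]


def compare_groups(
    stats_control: list[PatchStats], stats_test: list[PatchStats]
) -> tuple[pd.DataFrame, dict]:
    """Group means ± sem and percent difference of means, plus the raw table.

    Percent difference = ``100 * (mean_test / mean_control - 1)`` on group
    means; the per-movie table is the hand-off point for external
    hypothesis testing.
    """
    if not stats_control or not stats_test:
        raise ValueError("both groups must contain at least one movie")
    rows = []
    for group, stats_list in (("control", stats_control), ("test", stats_test)):
        for i, s in enumerate(stats_list):
            rows.append((group, i, s.frequency_per10um2_min, s.mean_duration_s, s.mean_rel_amplitude))
    table = pd.DataFrame(rows, columns=COMPARE_COLUMNS)
    summary: dict = {}
    for col in COMPARE_COLUMNS[2:]:
        by = table.groupby("group")[col]
        means = by.mean()
        sems = by.sem(ddof=1)
        pct = 100.0 * (means["test"] / means["control"] - 1.0) if means["control"] else float("nan")
        summary[col] = {
            "control_mean": float(means["control"]),
            "control_sem": float(sems["control"]) if np.isfinite(sems["control"]) else None,
            "test_mean": float(means["test"]),
            "test_sem": float(sems["test"]) if np.isfinite(sems["test"]) else None,
            "percent_difference": float(pct),
        }
    return table, summary
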