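"""High-level pipeline steps shared by the CLI and the analysis scripts."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import detection, model, stats, synthetic

log = logging.getLogger("droptubes")

__all__ = ["analyze_series", "analyze_frames", "synthesize_series"]


def analyze_frames(
    frames: Sequence[tuple[float, np.ndarray]],
    config: detection.DetectionConfig | None = None,
    mode: str = "unique",
    bin_width: float = 1.0,
    subsample: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, stats.Timecourse]:
    """Detect droplets and compute condensation statistics per frame.

    Droplets are detected independently in every frame (no tracking).
    ``subsample`` optionally analyzes a seeded random sample of at most
    that many detections per frame, mirroring per-timepoint sampling of a
    droplet subpopulation.  Returns the tidy per-droplet table and the
    population timecourse; raises if no frame yields a droplet.
    """
    from ._seeds import substream

    per_droplet = []
    tc_input = []
    any_droplets = False
    for k, (t, img) in enumerate(frames):
        dets = detection.detect_droplets(img, config, frame_index=k)
        if subsample is not None and len(dets) > subsample:
            rng = substream(seed, "subsample", k)
            idx = rng.choice(len(dets), size=subsample, replace=False)
            dets = [dets[i] for i in sorted(idx)]
        log.info("frame %d (t=%.1f min): %d droplets detected", k, t, len(dets))
        if not dets:
            continue
        any_droplets = True
        summaries = [
            stats.summarize_droplet(d, mode=mode, bin_width=bin_width, droplet_id=i)
            for i, d in enumerate(dets)
        ]
        df = stats.summaries_to_frame(summaries)
        df.insert(1, "time_min", t)
        df["center_row"] = [d.center_row for d in dets]
        df["center_col"] = [d.center_col for d in dets]
        df["radius_px"] = [d.radius_px for d in dets]
        per_droplet.append(df)
        tc_input.append((t, summaries))
    if not any_droplets:
        raise ValueError("no droplets detected in any frame")
    timecourse = stats.build_timecourse(tc_input)
    return pd.concat(per_droplet, ignore_index=True), timecourse


def analyze_series(
    directory: str | Path,
    outdir: str | Path,
    config: detection.DetectionConfig | None = None,
    mode: str = "unique",
    bin_width: float = 1.0,
    subsample: int | None = None,
    seed: int = 0,
) -> stats.Timecourse:
    """Analyze an on-disk image series; write per-droplet and timepoint CSVs."""
    from .io import read_series, write_provenance

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = read_series(directory)
    per_droplet, timecourse = analyze_frames(
        frames, config=config, mode=mode, bin_width=bin_width,
        subsample=subsample, seed=seed,
    )
    per_droplet.to_csv(outdir / "droplets.csv", index=False)
    timecourse.to_frame().to_csv(outdir / "timepoints.csv", index=False)
    cfg = config or detection.DetectionConfig()
    write_provenance(
        outdir / "analyze_provenance.json",
        {"detection": vars(cfg), "mode": mode, "bin_width": bin_width,
         "subsample": subsample, "input": str(directory)},
        seed=seed,
    )
    return timecourse


def synthesize_series(
    outdir: str | Path,
    n_droplets: int = 30,
    frame_shape: tuple[int, int] = (384, 384),
    radius_range_um: tuple[float, float] = (5.0, 20.0),
    fractions: Sequence[tuple[float, float]] | None = None,
    trajectory: "model.SimulationResult | None" = None,
    frame_times: Sequence[float] | None = None,
    imaging: synthetic.ImagingParams | None = None,
    seed: int = 0,
) -> list[synthetic.RenderedFrame]:
    """Generate a seeded synthetic droplet time series and write it to disk.

    Assembly over time comes either from an explicit (time, fraction) list,
    from an ODE trajectory, or defaults to a single all-free frame.
    """
    from .io import write_provenance

    if imaging is None:
        imaging = synthetic.ImagingParams(rng_seed=seed)
    population = synthetic.sample_droplet_population(
        n_droplets, frame_shape, radius_range_um=radius_range_um, seed=seed,
        pixel_size_um=imaging.pixel_size_um,
    )
    if trajectory is None and fractions is None:
        fractions = [(0.0, 0.0)]
    source = trajectory if trajectory is not None else fractions
    if frame_times is None:
        ts = np.asarray([t for t, _ in fractions]) if fractions is not None \
            else np.asarray(trajectory.t)
        frame_times = list(ts)
    frames = synthetic.render_timeseries(
        source, population, imaging, frame_times, frame_shape, seed=seed,
    )
    synthetic.write_frames(frames, outdir, imaging=imaging)
    write_provenance(
        Path(outdir) / "synthesize_provenance.json",
        {"n_droplets": n_droplets, "frame_shape": list(frame_shape),
         "radius_range_um": list(radius_range_um),
         "frame_times": [float(t) for t in frame_times],
         "imaging": vars(imaging)},
        seed=seed,
    )
    return frames
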