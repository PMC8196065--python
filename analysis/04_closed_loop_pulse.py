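#!/usr/bin/env python
"""Closed loop: kinetic pulse -> rendered droplet movie -> blind analysis.

Simulates the transcription + RNase H pulse, renders a six-frame droplet
time series from the trajectory, writes it to ``results/closed_loop/`` as
TIFFs with ground truth, analyzes the frames blind (detection + moment
statistics), and compares the recovered mean-skewness timecourse with the
simulated fraction of assembled tiles.
"""

import argparse
from pathlib import Path

import numpy as np

from droptubes import model as M
from droptubes import synthetic as syn
from droptubes.pipeline import analyze_frames

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--rnaseh", type=float, default=0.1)
    args = ap.parse_args()
    outdir = RESULTS / "closed_loop"
    outdir.mkdir(parents=True, exist_ok=True)
    # rendered TIFF frames are bulky binaries; they go to scratch/
    framedir = Path(__file__).resolve().parents[1] / "scratch" / "closed_loop_frames"

    res = M.simulate(M.pulse_params(H=args.rnaseh), t_end=600.0)
    times = list(np.linspace(0.0, 600.0, 6))
    f_at = np.interp(times, res.t, res.f)

    imaging = syn.ImagingParams(rng_seed=args.seed)
    pop = syn.sample_droplet_population(
        30, (384, 384), radius_range_um=(6, 18), seed=args.seed, border_margin_px=5
    )
    frames = syn.render_timeseries(res, pop, imaging, times, (384, 384),
                                   seed=args.seed)
    syn.write_frames(frames, framedir, imaging=imaging)

    per_droplet, tc = analyze_frames(
        [(fr.time_min, fr.image) for fr in frames], mode="pixels"
    )
    per_droplet.to_csv(outdir / "droplets.csv", index=False)
    table = tc.to_frame()
    table["true_fraction"] = f_at
    table.to_csv(outdir / "timepoints.csv", index=False)

    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    sk = table["mean_skewness"].to_numpy()
    offset = abs(int(np.argmax(sk)) - int(np.argmax(f_at)))
    print(
        f"\nmean skewness rises by {max(sk) - sk[0]:.2f} and falls by "
        f"{max(sk) - sk[-1]:.2f}; skewness peak within {offset} frame(s) of the "
        f"simulated assembly peak"
    )


if __name__ == "__main__":
    main()
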