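"""Synthetic fluorescence microscopy of DNA-nanotube assembly in droplets.

Generates seeded, ground-truth-annotated images of water-in-oil droplet
populations encapsulating fluorescently labelled DNA tiles.  Each droplet
carries a brightness budget proportional to its encapsulated tile
concentration; an ``assembled_fraction`` f of that budget is condensed into
bright worm-like-chain filaments (nanotubes / nanotube bundles) while the
remaining (1 - f) stays as a diffuse free-tile background whose projected
intensity follows the spherical chord depth 2*sqrt(R^2 - r^2).  Condensation
therefore redistributes signal without creating it, which is exactly the
premise of the skewness/kurtosis readout the analysis side measures.

Emulated features of the real data:

* vortex-emulsified ("shaken") droplet populations with a broad, log-uniform
  radius distribution (~1 to >20 um);
* stiff filaments (persistence length ~4-5 um) confined to the droplet
  interior, optionally localized near the droplet surface as the bundles
  that wrap around the inner droplet wall;
* 2D epifluorescence projection of a 3D droplet, including an out-of-focus
  contribution modelled as a radius-proportional defocus blur;
* unsaturated camera images: Poisson shot noise, Gaussian read noise,
  integer quantization, and a hard error if any pixel approaches the
  detector ceiling;
* droplet-to-droplet partitioning noise as a lognormal factor on the
  encapsulated tile amount.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from ._seeds import substream

__all__ = [
    "DropletSpec",
    "FilamentPath",
    "ImagingParams",
    "RenderedFrame",
    "PlacementError",
    "SaturationError",
    "sample_droplet_population",
    "simulate_filament",
    "default_filaments",
    "render_frame",
    "render_timeseries",
    "write_frames",
    "write_truth_csv",
]

#: photons per nM of tile per pixel of chord depth, at exposure_gain = 1.
BRIGHTNESS_PER_NM_PX = 0.15


class PlacementError(RuntimeError):
    """Raised when non-overlapping droplet placement fails."""


class SaturationError(ValueError):
    """Raised when a render would saturate the camera."""


@dataclass
class DropletSpec:
    """Ground-truth geometry and content of one droplet.

    ``tile_total`` is the encapsulated tile concentration in nM equivalents
    (it sets the droplet's brightness budget); ``assembled_fraction`` is the
    fraction of that budget condensed into filaments.
    """

    center_row: float
    center_col: float
    radius_um: float
    radius_px: float
    tile_total: float = 500.0
    assembled_fraction: float = 0.0
    surface_localized: bool = False

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.radius_px <= 0:
            raise ValueError("droplet radius must be positive")
        if not 0.0 <= self.assembled_fraction <= 1.0:
            raise ValueError("assembled_fraction must lie in [0, 1]")


@dataclass
class FilamentPath:
    """Discrete worm-like-chain path of one filament inside a droplet."""

    vertices: np.ndarray  # (n, 2) sub-pixel (row, col)
    step_um: float
    persistence_um: float


@dataclass
class ImagingParams:
    """Camera and optics model.

    ``exposure_gain`` scales the whole pre-noise image (signal plus
    background), mimicking exposure time; the condensation statistics must
    be invariant to it as long as nothing saturates.  ``defocus_fraction``
    is the sigma of the per-droplet out-of-focus blur as a fraction of the
    droplet radius.
    """

    pixel_size_um: float = 1.0
    psf_sigma_px: float = 1.0
    exposure_gain: float = 1.0
    read_noise_sd: float = 3.0
    bit_depth: int = 16
    background_level: float = 200.0
    defocus_fraction: float = 0.25
    filament_width_um: float = 0.5
    rng_seed: int = 0

    @property
    def saturation_ceiling(self) -> float:
        return 0.9 * (2**self.bit_depth - 1)


@dataclass
class RenderedFrame:
    """A rendered image plus the ground truth it was rendered from."""

    image: np.ndarray
    truth: list[DropletSpec]
    time_min: float = 0.0


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

def sample_droplet_population(
    n: int,
    frame_shape: tuple[int, int],
    radius_range_um: tuple[float, float] = (1.0, 20.0),
    seed: int = 0,
    pixel_size_um: float = 1.0,
    border_margin_px: float = 4.0,
    tile_total: float = 500.0,
    partitioning_cv: float = 0.2,
    surface_localized: bool = False,
    min_gap_px: float = 1.0,
    max_attempts_per_droplet: int = 500,
) -> list[DropletSpec]:
    """Place ``n`` non-overlapping droplets in a frame.

    Radii are drawn log-uniformly over ``radius_range_um``, emulating the
    broad size distribution of the shaken emulsification protocol.  Centers
    are rejection-sampled so that every pair of disks is separated by at
    least ``min_gap_px`` and no disk touches the border margin.
    ``partitioning_cv`` applies a per-droplet lognormal factor (sd of log =
    cv) to ``tile_total``, emulating partitioning noise; set 0 to disable.

    Raises
    ------
    PlacementError
        If a droplet cannot be placed within ``max_attempts_per_droplet``
        rejection attempts; the message reports how many were placed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    r_lo, r_hi = radius_range_um
    if r_lo <= 0 or r_hi < r_lo:
        raise ValueError("radius_range_um must satisfy 0 < min <= max")
    h, w = frame_shape
    r_hi_px = r_hi / pixel_size_um
    if 2 * (r_hi_px + border_margin_px) >= min(h, w):
        raise ValueError(
            "frame too small to hold one droplet of the maximum radius"
        )
    rng = substream(seed, "population")
    placed: list[DropletSpec] = []
    for i in range(n):
        r_um = math.exp(rng.uniform(math.log(r_lo), math.log(r_hi)))
        r_px = r_um / pixel_size_um
        lo_r = border_margin_px + r_px
        ok = False
        for _ in range(max_attempts_per_droplet):
            cr = rng.uniform(lo_r, h - 1 - lo_r)
            cc = rng.uniform(lo_r, w - 1 - lo_r)
            if all(
                math.hypot(cr - d.center_row, cc - d.center_col)
                > r_px + d.radius_px + min_gap_px
                for d in placed
            ):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"placed only {len(placed)} of {n} droplets before running "
                f"out of attempts; reduce n or the maximum radius"
            )
        t = tile_total
        if partitioning_cv > 0:
            t *= rng.lognormal(mean=0.0, sigma=partitioning_cv)
        placed.append(
            DropletSpec(
                center_row=cr,
                center_col=cc,
                radius_um=r_um,
                radius_px=r_px,
                tile_total=t,
                surface_localized=surface_localized,
            )
        )
    return placed


# ---------------------------------------------------------------------------
# filaments
# ---------------------------------------------------------------------------

def simulate_filament(
    droplet: DropletSpec,
    length_um: float,
    persistence_um: float = 4.5,
    step_um: float = 0.1,
    pixel_size_um: float = 1.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> FilamentPath:
    """Simulate a confined discrete worm-like chain inside a droplet.

    Turning angles between consecutive steps are Gaussian with variance
    2*step/persistence, so the mean cosine of the turning angle equals
    exp(-step/persistence) — the 2D worm-like-chain tangent decorrelation.
    The chain is confined to the droplet disk (shrunk by one step) by
    specular reflection at the boundary.  With ``droplet.surface_localized``
    the chain is instead confined to an annulus spanning 0.85-1.0 of the
    radius, emulating bundles wrapping the inner droplet surface.
    """
    if length_um <= 0:
        raise ValueError("length_um must be positive")
    if persistence_um <= 0:
        raise ValueError("persistence_um must be positive")
    step_px = step_um / pixel_size_um
    r_out = droplet.radius_px - step_px
    if r_out <= step_px:
        raise ValueError("droplet radius must exceed one step")
    r_in = 0.85 * droplet.radius_px if droplet.surface_localized else 0.0
    if r_in >= r_out:  # tiny droplet: fall back to full-disk confinement
        r_in = 0.0
    if rng is None:
        rng = substream(seed, "filament")
    center = np.array([droplet.center_row, droplet.center_col])

    # start at a uniform point of the allowed region
    u = rng.uniform(r_in**2, r_out**2)
    rho = math.sqrt(u)
    phi = rng.uniform(0, 2 * math.pi)
    pos = center + rho * np.array([math.cos(phi), math.sin(phi)])
    theta = rng.uniform(0, 2 * math.pi)

    n_steps = max(1, int(round(length_um / step_um)))
    sigma = math.sqrt(2.0 * step_um / persistence_um)
    verts = np.empty((n_steps + 1, 2))
    verts[0] = pos
    for i in range(n_steps):
        theta += rng.normal(0.0, sigma)
        for _ in range(16):
            cand = pos + step_px * np.array([math.cos(theta), math.sin(theta)])
            rad = np.linalg.norm(cand - center)
            if r_in <= rad <= r_out:
                break
            # specular bounce off the violated circular boundary
            nhat = (cand - center) / max(rad, 1e-12)
            d = np.array([math.cos(theta), math.sin(theta)])
            d = d - 2.0 * float(d @ nhat) * nhat
            theta = math.atan2(d[1], d[0])
        else:  # pathological corner: point back toward the allowed annulus
            target = center + 0.5 * (r_in + r_out) * (pos - center) / max(
                np.linalg.norm(pos - center), 1e-12
            )
            d = target - pos
            theta = math.atan2(d[1], d[0])
            cand = pos + step_px * np.array([math.cos(theta), math.sin(theta)])
        pos = cand
        verts[i + 1] = pos
    return FilamentPath(vertices=verts, step_um=step_um, persistence_um=persistence_um)


def default_filaments(
    droplet: DropletSpec,
    pixel_size_um: float = 1.0,
    persistence_um: float = 4.5,
    density: float = 0.095,
    length_exponent: float = 2.5,
    bundling: float = 0.5,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> list[FilamentPath]:
    """Generate a plausible filament set for a droplet's assembled mass.

    Nanotube number and length per droplet are not quantified in the data
    this generator emulates, so a simple scaling is used: the total contour
    length is set by the droplet's nucleation capacity
    (L = density * R_um^length_exponent, between cross-section and volume
    scaling) and *shrinks* mildly as assembly proceeds (factor
    1 - bundling * f), emulating the observed joining of nanotubes into
    fewer, thicker bundles over time.  The assembled mass f * tile_total is
    spread over that contour at render time, so per-pixel filament
    brightness grows with f while the bright footprint stays roughly
    constant — condensation sharpens contrast rather than flooding the
    droplet with bright pixels.  Filaments are roughly one droplet diameter
    long each.
    """
    f = droplet.assembled_fraction
    if f <= 0:
        return []
    if rng is None:
        rng = substream(seed, "filaments")
    total_um = density * droplet.radius_um**length_exponent * (1.0 - bundling * f)
    total_um = max(total_um, 1.0)
    per_fil = 2.0 * droplet.radius_um
    n_fil = max(1, int(math.ceil(total_um / per_fil)))
    each = total_um / n_fil
    return [
        simulate_filament(
            droplet,
            length_um=each,
            persistence_um=persistence_um,
            pixel_size_um=pixel_size_um,
            rng=rng,
        )
        for _ in range(n_fil)
    ]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _splat_polyline(patch: np.ndarray, verts: np.ndarray, total: float) -> None:
    """Bilinearly deposit ``total`` intensity uniformly along a polyline."""
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    length = float(seg_len.sum())
    if length <= 0:
        pts = verts[:1]
        weights = np.array([total])
    else:
        # sample points every quarter pixel along the arc
        n_pts = max(2, int(math.ceil(length / 0.25)))
        s = np.linspace(0.0, length, n_pts)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        rows = np.interp(s, cum, verts[:, 0])
        cols = np.interp(s, cum, verts[:, 1])
        pts = np.stack([rows, cols], axis=1)
        weights = np.full(n_pts, total / n_pts)
    h, w = patch.shape
    r0 = np.floor(pts[:, 0]).astype(int)
    c0 = np.floor(pts[:, 1]).astype(int)
    fr = pts[:, 0] - r0
    fc = pts[:, 1] - c0
    for dr, dc, wt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        m = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.add.at(patch, (rr[m], cc[m]), (weights * wt)[m])


def _render_droplet_patch(
    droplet: DropletSpec,
    filaments: Sequence[FilamentPath],
    imaging: ImagingParams,
) -> tuple[np.ndarray, int, int]:
    """Render one droplet's noise-free signal into a local patch.

    Returns (patch, row_offset, col_offset).  The patch total equals
    BRIGHTNESS_PER_NM_PX * tile_total * (numeric chord-depth integral),
    independent of assembled_fraction: condensation only redistributes.
    """
    R = droplet.radius_px
    f = droplet.assembled_fraction
    # per-droplet defocus chosen so the total blur on the free-tile dome
    # (defocus combined with the global PSF) is defocus_fraction * R: the
    # rendered droplet is then scale-free and the condensation statistics
    # carry no systematic radius dependence.
    target = imaging.defocus_fraction * R
    sigma_def = math.sqrt(max(target**2 - imaging.psf_sigma_px**2, 0.0))
    pad = int(math.ceil(R + 3 * sigma_def + 4))
    r0 = int(math.floor(droplet.center_row)) - pad
    c0 = int(math.floor(droplet.center_col)) - pad
    size = 2 * pad + 1
    rows = np.arange(size)[:, None] + r0 - droplet.center_row
    cols = np.arange(size)[None, :] + c0 - droplet.center_col
    rr2 = rows**2 + cols**2
    depth = 2.0 * np.sqrt(np.maximum(R**2 - rr2, 0.0))
    depth_sum = float(depth.sum())

    k = BRIGHTNESS_PER_NM_PX * droplet.tile_total
    patch = k * (1.0 - f) * depth
    if sigma_def > 0:
        patch = gaussian_filter(patch, sigma_def, mode="constant")

    if f > 0:
        if not filaments:
            raise ValueError(
                "droplet with assembled_fraction > 0 needs filaments "
                "(use default_filaments)"
            )
        fil_patch = np.zeros_like(patch)
        assembled_total = k * f * depth_sum
        per_fil = assembled_total / len(filaments)
        for fil in filaments:
            verts = fil.vertices - np.array([r0, c0])
            _splat_polyline(fil_patch, verts, per_fil)
        sigma_w = imaging.filament_width_um / imaging.pixel_size_um / 2.355
        if sigma_w > 0:
            fil_patch = gaussian_filter(fil_patch, sigma_w, mode="constant")
        patch = patch + fil_patch
    return patch, r0, c0


def render_frame(
    droplets: Sequence[DropletSpec],
    filaments: Mapping[int, Sequence[FilamentPath]] | None,
    imaging: ImagingParams,
    frame_shape: tuple[int, int],
    time_min: float = 0.0,
    noise_key: int = 0,
) -> RenderedFrame:
    """Render one camera frame of a droplet population.

    ``filaments`` maps droplet index to its filament paths; it may be None
    when every droplet has assembled_fraction 0.  Noise is drawn from the
    substream (imaging.rng_seed, "noise", noise_key), so repeated calls with
    identical arguments are bit-identical and frames of a time series get
    independent noise via distinct ``noise_key`` values.

    Raises
    ------
    SaturationError
        If any pixel would reach 90% of the camera's dynamic range; lower
        ``exposure_gain``.
    """
    ideal = np.zeros(frame_shape, dtype=float)
    for i, d in enumerate(droplets):
        fils = filaments.get(i, []) if filaments else []
        patch, r0, c0 = _render_droplet_patch(d, fils, imaging)
        rs, cs = patch.shape
        fr0, fc0 = max(r0, 0), max(c0, 0)
        fr1, fc1 = min(r0 + rs, frame_shape[0]), min(c0 + cs, frame_shape[1])
        if fr1 <= fr0 or fc1 <= fc0:
            continue
        ideal[fr0:fr1, fc0:fc1] += patch[fr0 - r0 : fr1 - r0, fc0 - c0 : fc1 - c0]

    if imaging.psf_sigma_px > 0:
        ideal = gaussian_filter(ideal, imaging.psf_sigma_px, mode="constant")
    ideal = imaging.exposure_gain * (ideal + imaging.background_level)

    rng = substream(imaging.rng_seed, "noise", noise_key)
    noisy = rng.poisson(ideal).astype(float)
    noisy += rng.normal(0.0, imaging.read_noise_sd, size=ideal.shape)
    noisy = np.clip(np.rint(noisy), 0, None)
    ceiling = imaging.saturation_ceiling
    if noisy.max() >= ceiling:
        raise SaturationError(
            f"rendered maximum {noisy.max():.0f} reaches 90% of the "
            f"{imaging.bit_depth}-bit range; lower exposure_gain"
        )
    dtype = np.uint16 if imaging.bit_depth <= 16 else np.uint32
    return RenderedFrame(
        image=noisy.astype(dtype),
        truth=[dataclasses.replace(d) for d in droplets],
        time_min=time_min,
    )


def render_timeseries(
    trajectory,
    population: Sequence[DropletSpec],
    imaging: ImagingParams,
    frame_times: Sequence[float],
    frame_shape: tuple[int, int],
    fraction_jitter_sd: float = 0.0,
    filament_density: float = 0.095,
    persistence_um: float = 4.5,
    seed: int | None = None,
) -> list[RenderedFrame]:
    """Render one frame per requested time of an assembly trajectory.

    ``trajectory`` is either an object with ``t`` and ``f`` arrays (e.g. a
    SimulationResult from the assembly model) or an explicit sequence of
    (time_min, fraction) pairs; the assembled fraction of every droplet at a
    frame time is interpolated from it (optionally jittered per droplet by a
    truncated Gaussian of sd ``fraction_jitter_sd``).  Filament number and
    length scale with each droplet's assembled mass and are regrown
    independently per frame — droplets are not tracked between frames, so
    per-frame filament realizations are independent too.
    """
    if len(frame_times) == 0:
        raise ValueError("frame_times must not be empty")
    if hasattr(trajectory, "t") and hasattr(trajectory, "f"):
        tgrid = np.asarray(trajectory.t, dtype=float)
        fgrid = np.asarray(trajectory.f, dtype=float)
    else:
        pairs = np.asarray(list(trajectory), dtype=float)
        tgrid, fgrid = pairs[:, 0], pairs[:, 1]
    if np.min(frame_times) < tgrid[0] or np.max(frame_times) > tgrid[-1]:
        raise ValueError("frame_times outside trajectory time range")
    if seed is None:
        seed = imaging.rng_seed
    frames = []
    for k, t in enumerate(frame_times):
        f_t = float(np.interp(t, tgrid, fgrid))
        rng = substream(seed, "timeseries", k)
        droplets = []
        filaments: dict[int, list[FilamentPath]] = {}
        for i, base in enumerate(population):
            f_i = f_t
            if fraction_jitter_sd > 0:
                f_i = float(np.clip(f_t + rng.normal(0, fraction_jitter_sd), 0, 1))
            d = dataclasses.replace(base, assembled_fraction=f_i)
            droplets.append(d)
            filaments[i] = default_filaments(
                d,
                pixel_size_um=imaging.pixel_size_um,
                persistence_um=persistence_um,
                density=filament_density,
                rng=rng,
            )
        frames.append(
            render_frame(
                droplets, filaments, imaging, frame_shape, time_min=float(t),
                noise_key=k,
            )
        )
    return frames


def render_single_droplet(
    radius_px: float,
    assembled_fraction: float = 0.0,
    seed: int = 0,
    tile_total: float = 500.0,
    imaging: ImagingParams | None = None,
) -> RenderedFrame:
    """Render one droplet centered in its own minimal frame.

    Convenience for moment-statistics studies at prescribed assembled
    fractions, where droplet isolation removes any detection influence.
    """
    pad = int(math.ceil(radius_px * 1.6 + 8))
    d = DropletSpec(
        center_row=pad, center_col=pad, radius_um=radius_px, radius_px=radius_px,
        tile_total=tile_total, assembled_fraction=assembled_fraction,
    )
    fils = default_filaments(d, seed=seed) if assembled_fraction > 0 else None
    if imaging is None:
        imaging = ImagingParams(rng_seed=seed)
    else:
        imaging = dataclasses.replace(imaging, rng_seed=seed)
    return render_frame(
        [d], {0: fils} if fils else None, imaging, (2 * pad + 1, 2 * pad + 1)
    )


# ---------------------------------------------------------------------------
# persistence to disk
# ---------------------------------------------------------------------------

def write_frames(
    frames: Sequence[RenderedFrame],
    outdir: str | Path,
    stem: str = "frame",
    imaging: ImagingParams | None = None,
) -> list[Path]:
    """Write frames as 16-bit grayscale TIFFs plus truth CSV and JSON sidecar.

    Also writes ``manifest.csv`` (filename, time_min) so the analysis stage
    can map frames to acquisition times.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    rows = []
    for k, fr in enumerate(frames):
        p = outdir / f"{stem}_{k:03d}.tif"
        tifffile.imwrite(p, fr.image)
        paths.append(p)
        rows.append({"filename": p.name, "time_min": fr.time_min})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    write_truth_csv(frames, outdir / "truth.csv")
    if imaging is not None:
        with open(outdir / "params.json", "w") as fh:
            json.dump(dataclasses.asdict(imaging), fh, indent=2)
    return paths


def write_truth_csv(frames: Sequence[RenderedFrame], path: str | Path) -> None:
    rows = []
    for k, fr in enumerate(frames):
        for i, d in enumerate(fr.truth):
            rows.append(
                {
                    "frame": k,
                    "time_min": fr.time_min,
                    "droplet_id": i,
                    "center_row": d.center_row,
                    "center_col": d.center_col,
                    "radius_px": d.radius_px,
                    "assembled_fraction": d.assembled_fraction,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "frame", "time_min", "droplet_id", "center_row", "center_col",
            "radius_px", "assembled_fraction",
        ],
    ).to_csv(path, index=False)
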