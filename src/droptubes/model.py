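"""Deterministic ODE model of RNA-triggered DNA tile assembly.

Mechanism (all concentrations in nM, time in minutes):

* A synthetic gene template G is transcribed by T7 RNA polymerase into a
  trigger RNA R at rate ``k_tx * G * a``; the polymerase's relative
  activity ``a`` decays exponentially at rate ``delta`` (transcription is a
  burst that fades over the experiment).
* Trigger RNA activates inactive tiles Ti (second order, ``k_act``),
  producing active free tiles Ta that carry a DNA:RNA hybrid sticky end.
  Free RNA itself is not degraded (no hybrid until bound).
* Active tiles polymerize by cooperative nucleation (``k_nuc * Ta^n_nuc``
  creating nuclei N and consuming n_nuc tiles each) and elongation
  (``k_on * Ta * N``); filaments shed tiles back into the active pool at
  ``k_off * N``.
* RNase H deactivates only *free* active tiles (it degrades the RNA half
  of the hybrid sticky end): rate ``k_deg * H * Ta``.  A fraction
  ``w_frac`` of deactivation events yields waste complexes W that can no
  longer be re-activated (incomplete degradation products); the rest
  return to the inactive pool.

Tiles are conserved exactly: Ti + Ta + P + W = T_total.  With transcription
decay (delta > 0) and RNase H present the model produces a pulse of
assembled fraction f = P/T_total whose height and duration shrink and whose
onset is delayed as H increases; without RNase H, f rises monotonically and
both its kinetics and its plateau grow with the gene concentration G.

Rate-constant defaults are order-of-magnitude choices producing these
regimes under the standard experimental conditions (500 nM inactive tile,
7.5-100 nM gene, 0.025-0.1 U/uL RNase H); they are NOT fitted to data.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ModelState",
    "RateParams",
    "SimulationResult",
    "PulseMetrics",
    "derivatives",
    "simulate",
    "pulse_metrics",
    "sweep_parameter",
    "two_tile_params",
    "pulse_params",
    "apply_peg",
    "load_params_toml",
]

_STATE_FIELDS = ("Ti", "Ta", "P", "N", "R", "W", "a")

#: depolymerization saturates as P -> 0 (scale in nM): the shedding flux is
#: k_off * N * P / (P + _DEPOL_SAT_NM), so filaments stop releasing tiles
#: when no polymerized mass is left.  Far from empty (P >> 1e-3 nM) this is
#: indistinguishable from plain k_off * N; near empty it keeps P >= 0 and
#: tile conservation exact instead of letting the polymer pool go negative.
_DEPOL_SAT_NM = 1e-3


@dataclass
class ModelState:
    """Concentrations (nM) plus RNAP relative activity ``a`` (dimensionless)."""

    Ti: float = 500.0  # inactive tile
    Ta: float = 0.0    # active free tile
    P: float = 0.0     # polymerized tile mass (tile equivalents)
    N: float = 0.0     # nucleus / filament number density
    R: float = 0.0     # free trigger RNA
    W: float = 0.0     # waste-sequestered tile
    a: float = 1.0     # RNAP relative activity, in [0, 1]

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(**dict(zip(_STATE_FIELDS, map(float, y))))


@dataclass
class RateParams:
    """Kinetic constants; see module docstring for the mechanism.

    Units: first-order rates 1/min; second-order rates 1/nM/min; ``k_nuc``
    nM^(1-n_nuc)/min; ``k_deg`` 1/(U/uL)/min with ``H`` in U/uL (the enzyme
    is specified in activity units, so k_deg absorbs the conversion).
    """

    k_tx: float = 0.2      # transcription, 1/min per nM gene
    G: float = 100.0       # gene template, nM
    delta: float = 0.02    # RNAP activity decay, 1/min (half-life ~35 min)
    k_act: float = 2e-3    # tile activation by trigger RNA, 1/nM/min
    n_nuc: int = 3         # nucleus size, tiles
    k_nuc: float = 3e-6    # nucleation, nM^(1-n_nuc)/min
    k_on: float = 1e-2     # elongation, 1/nM/min
    k_off: float = 5e-2    # depolymerization, 1/min
    k_deg: float = 2.0     # RNase H deactivation, 1/(U/uL)/min
    H: float = 0.0         # RNase H, U/uL
    w_frac: float = 0.2    # waste fraction per deactivation event
    T_total: float = 500.0 # total tile, nM

    def __post_init__(self) -> None:
        if self.n_nuc < 2:
            raise ValueError("n_nuc must be >= 2")
        if not 0.0 <= self.w_frac <= 1.0:
            raise ValueError("w_frac must lie in [0, 1]")
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def initial_state(self) -> ModelState:
        return ModelState(Ti=self.T_total, Ta=0.0, P=0.0, N=0.0, R=0.0, W=0.0, a=1.0)


def _rhs(t: float, y: np.ndarray, p: RateParams) -> np.ndarray:
    Ti, Ta, P, N, R, a = y[0], y[1], y[2], y[3], y[4], y[6]
    Ta_pos = max(Ta, 0.0)
    P_pos = max(P, 0.0)
    nuc = p.k_nuc * Ta_pos**p.n_nuc
    elong = p.k_on * Ta * N
    depol = p.k_off * N * (P_pos / (P_pos + _DEPOL_SAT_NM))
    act = p.k_act * Ti * R
    deact = p.k_deg * p.H * Ta
    dR = p.k_tx * p.G * a - act
    da = -p.delta * a
    dTi = -act + (1.0 - p.w_frac) * deact
    dW = p.w_frac * deact
    dN = nuc
    dP = p.n_nuc * nuc + elong - depol
    dTa = act - deact - p.n_nuc * nuc - elong + depol
    return np.array([dTi, dTa, dP, dN, dR, dW, da])


def derivatives(state: ModelState, params: RateParams) -> ModelState:
    """Time derivatives of the model state (validated public entry point)."""
    y = state.to_array()
    if np.any(y[:6] < 0):
        raise ValueError("state concentrations must be non-negative")
    return ModelState.from_array(_rhs(0.0, y, params))


@dataclass
class SimulationResult:
    """Integrated trajectory with fraction of assembled tiles f = P/T_total."""

    t: np.ndarray
    states: np.ndarray  # (7, n) rows ordered Ti, Ta, P, N, R, W, a
    f: np.ndarray
    params: RateParams

    def state_at(self, idx: int) -> ModelState:
        return ModelState.from_array(self.states[:, idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states.T, columns=list(_STATE_FIELDS))
        df.insert(0, "t", self.t)
        df["f"] = self.f
        return df


def simulate(
    params: RateParams,
    init: ModelState | None = None,
    t_end: float = 600.0,
    n_points: int = 601,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the model with a stiff-capable adaptive solver.

    Small negative excursions (roundoff) are clipped to zero; excursions
    below ``-10 * atol`` additionally raise a warning.  Integration failure
    raises with the solver's diagnostics and the parameters echoed.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if init is None:
        init = params.initial_state()
    y0 = init.to_array()
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        _rhs, (0.0, t_end), y0, args=(params,), method=method,
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed: {sol.message}; params={params}"
        )
    y = sol.y
    worst = float(y.min())
    if worst < -10.0 * atol:
        warnings.warn(
            f"clipping negative state excursion {worst:.3e} to zero",
            RuntimeWarning,
        )
    y = np.clip(y, 0.0, None)
    f = y[2] / params.T_total if params.T_total > 0 else np.zeros_like(sol.t)
    return SimulationResult(t=sol.t, states=y, f=f, params=params)


@dataclass
class PulseMetrics:
    """Summary of a (possibly right-censored) assembly pulse."""

    peak_height: float
    t_peak: float
    duration_above: float
    t_half_rise: float
    threshold: float
    right_censored: bool = False


def _crossings(t: np.ndarray, f: np.ndarray, level: float) -> list[float]:
    """Linearly interpolated times where f crosses ``level``."""
    out = []
    s = f - level
    for i in range(len(t) - 1):
        if s[i] == 0.0:
            out.append(float(t[i]))
        elif s[i] * s[i + 1] < 0:
            frac = s[i] / (s[i] - s[i + 1])
            out.append(float(t[i] + frac * (t[i + 1] - t[i])))
    if s[-1] == 0.0:
        out.append(float(t[-1]))
    return out


def pulse_metrics(result: SimulationResult, threshold: float = 0.1) -> PulseMetrics:
    """Peak height/time, time above threshold, and half-rise time of f(t).

    The peak is refined by a parabola through the three grid points around
    the maximum; the duration above threshold is the total measure of
    {t : f(t) > threshold} with interpolated crossings.  A trajectory still
    above threshold at the end of the window is flagged right-censored.
    """
    t, f = result.t, result.f
    i = int(np.argmax(f))
    peak, t_peak = float(f[i]), float(t[i])
    if 0 < i < len(t) - 1:
        y0, y1, y2 = f[i - 1], f[i], f[i + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-15:
            shift = 0.5 * (y0 - y2) / denom
            if abs(shift) <= 1.0:
                dt = t[i + 1] - t[i]
                t_peak = float(t[i] + shift * dt)
                peak = float(y1 - 0.25 * (y0 - y2) * shift)

    # duration above threshold
    above = f > threshold
    duration = 0.0
    censored = bool(above[-1])
    if above.any():
        cross = _crossings(t, f, threshold)
        bounds = []
        if above[0]:
            bounds.append(float(t[0]))
        bounds.extend(cross)
        if censored:
            bounds.append(float(t[-1]))
        for j in range(0, len(bounds) - 1, 2):
            duration += bounds[j + 1] - bounds[j]

    half = peak / 2.0
    t_half = float("nan")
    idx = np.nonzero(f >= half)[0]
    if idx.size:
        j = int(idx[0])
        if j == 0:
            t_half = float(t[0])
        else:
            frac = (half - f[j - 1]) / (f[j] - f[j - 1])
            t_half = float(t[j - 1] + frac * (t[j] - t[j - 1]))
    return PulseMetrics(
        peak_height=peak, t_peak=t_peak, duration_above=float(duration),
        t_half_rise=t_half, threshold=threshold, right_censored=censored,
    )


def sweep_parameter(
    base: RateParams,
    name: str,
    values: Sequence[float],
    init: ModelState | None = None,
    t_end: float = 600.0,
    n_points: int = 601,
    threshold: float = 0.1,
) -> list[tuple[float, SimulationResult, PulseMetrics]]:
    """Re-simulate for each value of one named parameter (shared init)."""
    valid = [f.name for f in dataclasses.fields(RateParams)]
    if name not in valid:
        raise ValueError(f"unknown parameter {name!r}; valid: {', '.join(valid)}")
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    out = []
    for v in values:
        p = dataclasses.replace(base, **{name: v})
        res = simulate(p, init=init, t_end=t_end, n_points=n_points)
        out.append((float(v), res, pulse_metrics(res, threshold)))
    return out


def sweep_to_frame(
    sweep: Sequence[tuple[float, SimulationResult, PulseMetrics]], name: str
) -> pd.DataFrame:
    """Tidy long-format trajectory table for a parameter sweep."""
    parts = []
    for v, res, _ in sweep:
        df = res.to_frame()
        df.insert(0, name, v)
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def two_tile_params(T_total: float = 100.0, **over) -> tuple[RateParams, ModelState]:
    """Preset for the two-tile design: all tiles active at t=0, no enzymes.

    Mixing pre-annealed complementary tiles starts assembly immediately, so
    activation/transcription/degradation are switched off and the initial
    state holds the full tile budget in the active pool.
    """
    p = RateParams(k_tx=0.0, G=0.0, k_act=0.0, k_deg=0.0, H=0.0,
                   T_total=T_total, **over)
    s = ModelState(Ti=0.0, Ta=T_total, P=0.0, N=0.0, R=0.0, W=0.0, a=1.0)
    return p, s


def pulse_params(H: float = 0.05, G: float = 100.0, **over) -> RateParams:
    """Preset for the transcription + RNase H pulse experiments."""
    return RateParams(G=G, H=H, **over)


def apply_peg(params: RateParams, factor: float = 3.0) -> RateParams:
    """Crowding-agent preset: multiply nucleation and elongation rates.

    PEG accelerates assembly; it is represented purely as this rate factor
    (no crowding physics).
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return dataclasses.replace(
        params, k_nuc=params.k_nuc * factor, k_on=params.k_on * factor
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_params_toml(path: str | Path) -> RateParams:
    """Read RateParams from a TOML file with a [rates] table (or flat keys)."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    table = data.get("rates", data)
    valid = {f.name for f in dataclasses.fields(RateParams)}
    unknown = set(table) - valid
    if unknown:
        raise ValueError(f"unknown parameters in {path}: {sorted(unknown)}")
    return RateParams(**table)


def write_result(result: SimulationResult, outdir: str | Path, stem: str = "trajectory",
                 threshold: float = 0.1) -> None:
    """Write trajectory CSV plus a JSON sidecar of parameters and metrics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(outdir / f"{stem}.csv", index=False)
    m = pulse_metrics(result, threshold)
    with open(outdir / f"{stem}.json", "w") as fh:
        json.dump(
            {"params": dataclasses.asdict(result.params),
             "metrics": dataclasses.asdict(m)},
            fh, indent=2,
        )
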