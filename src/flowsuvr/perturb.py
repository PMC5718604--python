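"""Flow perturbation at constant V_ND and its effect on SUVR.

A regional blood-flow change is modelled as a common scaling of the delivery
rate K1 and the clearance rate k2, which leaves the non-displaceable
distribution volume V_ND = K1/k2 (and hence V_T) untouched while shifting
the kinetics' time scale. SUVR is the duration-weighted target/reference
activity ratio over a late uptake window (default 50-60 min p.i.); the
flow-induced bias is

    dSUVR = 100 (SUVR_simulated - SUVR_baseline) / SUVR_baseline   [%]

and a simultaneous, equal flow change in target and reference composes
multiplicatively:

    dSUVR_global = 100 [(1 + dSUVR_target/100)(1 + dSUVR_ref/100) - 1].

The composition is exact because SUVR is a ratio of two independently
scaled terms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .kinetics import (
    DEFAULT_FRAME_SCHEDULE,
    FrameSchedule,
    InputFunction,
    KineticParams,
    RegionalTAC,
    simulate_tac,
)

__all__ = [
    "PerturbationSpec",
    "DeltaSUVRCurve",
    "DEFAULT_GRID",
    "DEFAULT_WINDOW",
    "perturb_flow",
    "compute_suvr",
    "delta_suvr",
    "compose_global",
    "sweep_delta_suvr",
    "fit_cubic",
    "delta_suvr_time_course",
    "relative_delivery",
]

Mode = Literal["target-only", "reference-only", "global"]

DEFAULT_GRID: tuple[float, ...] = (-40.0, -20.0, -10.0, -5.0, 5.0, 10.0, 20.0, 40.0)
DEFAULT_WINDOW: tuple[float, float] = (50.0, 60.0)


@dataclass(frozen=True)
class PerturbationSpec:
    """What to perturb and how to read out the effect."""

    mode: Mode = "target-only"
    grid_pct: tuple[float, ...] = DEFAULT_GRID
    window: tuple[float, float] = DEFAULT_WINDOW
    target: str = "precuneus"
    reference: str = "CB"

    def __post_init__(self) -> None:
        if self.mode not in ("target-only", "reference-only", "global"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(g <= -100 for g in self.grid_pct):
            raise ValueError("grid values must exceed -100%")
        if self.window[1] <= self.window[0] or self.window[0] < 0:
            raise ValueError("invalid SUVR window")


@dataclass
class DeltaSUVRCurve:
    """dSUVR (%) against dK1 (%) with an optional cubic summary fit."""

    grid_pct: np.ndarray
    delta_suvr_pct: np.ndarray
    baseline_suvr: float
    mode: str
    target: str
    reference: str
    cubic_coeffs: np.ndarray | None = None  # highest degree first
    r_squared: float | None = None


def perturb_flow(p: KineticParams, dk1_pct: float) -> KineticParams:
    """Scale K1 and k2 together by (1 + dK1%/100); k3, k4, Vb untouched.

    The common factor cancels in V_ND = K1/k2, so V_T and BP_ND are invariant.
    """
    if dk1_pct <= -100:
        raise ValueError("dK1 must exceed -100%")
    f = 1.0 + dk1_pct / 100.0
    return replace(p, K1=p.K1 * f, k2=p.k2 * f)


def _window_mean(tac: RegionalTAC, window: tuple[float, float]) -> float:
    """Overlap-duration-weighted mean of frame activities within the window."""
    lo, hi = window
    overlap = np.minimum(tac.schedule.ends, hi) - np.maximum(tac.schedule.starts, lo)
    overlap = np.clip(overlap, 0.0, None)
    total = overlap.sum()
    if total <= 0:
        raise ValueError(f"no frame intersects the window [{lo}, {hi}] min")
    return float((tac.values * overlap).sum() / total)


def compute_suvr(
    target: RegionalTAC,
    reference: RegionalTAC,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> float:
    """SUVR = windowed mean target activity / windowed mean reference activity."""
    if target.schedule != reference.schedule:
        raise ValueError("target and reference TACs must share a frame schedule")
    num = _window_mean(target, window)
    den = _window_mean(reference, window)
    if den <= 0:
        raise ValueError("reference activity must be positive in the window")
    return num / den


def delta_suvr(suvr_sim: float, suvr_base: float) -> float:
    """Percent change of a simulated SUVR from its baseline."""
    if suvr_base <= 0:
        raise ValueError("baseline SUVR must be positive")
    return 100.0 * (suvr_sim - suvr_base) / suvr_base


def compose_global(d_target: float, d_ref: float) -> float:
    """Global (target+reference) effect from the two single-region effects."""
    if d_target <= -100 or d_ref <= -100:
        raise ValueError("component changes must exceed -100%")
    return 100.0 * ((1.0 + d_target / 100.0) * (1.0 + d_ref / 100.0) - 1.0)


def relative_delivery(k1_target: float, k1_ref: float) -> float:
    """Relative delivery rate R1 = K1_target / K1_reference."""
    if k1_ref <= 0:
        raise ValueError("reference K1 must be positive")
    return k1_target / k1_ref


def sweep_delta_suvr(
    target_p: KineticParams,
    ref_p: KineticParams,
    input_function: InputFunction,
    spec: PerturbationSpec = PerturbationSpec(),
    frames: FrameSchedule = DEFAULT_FRAME_SCHEDULE,
    fit: bool = True,
) -> DeltaSUVRCurve:
    """dSUVR across the dK1 grid for one perturbation mode.

    Only the perturbed region's TAC is re-simulated per grid point; a grid
    point of 0 therefore yields exactly 0. The cubic summary fit is attached
    when the grid has at least five distinct points and ``fit`` is True.
    """
    base_target = simulate_tac(target_p, input_function, frames, region=spec.target)
    base_ref = simulate_tac(ref_p, input_function, frames, region=spec.reference)
    suvr_base = compute_suvr(base_target, base_ref, spec.window)

    deltas = []
    for g in spec.grid_pct:
        if g == 0:
            deltas.append(0.0)
            continue
        tac_t = base_target
        tac_r = base_ref
        if spec.mode in ("target-only", "global"):
            tac_t = simulate_tac(
                perturb_flow(target_p, g), input_function, frames, region=spec.target
            )
        if spec.mode in ("reference-only", "global"):
            tac_r = simulate_tac(
                perturb_flow(ref_p, g), input_function, frames, region=spec.reference
            )
        deltas.append(delta_suvr(compute_suvr(tac_t, tac_r, spec.window), suvr_base))

    curve = DeltaSUVRCurve(
        grid_pct=np.asarray(spec.grid_pct, dtype=float),
        delta_suvr_pct=np.asarray(deltas),
        baseline_suvr=suvr_base,
        mode=spec.mode,
        target=spec.target,
        reference=spec.reference,
    )
    if fit and len(set(spec.grid_pct)) >= 5:
        fit_cubic(curve)
    return curve


def fit_cubic(curve: DeltaSUVRCurve) -> tuple[np.ndarray, float]:
    """Unweighted OLS cubic of dSUVR on dK1; stores coefficients and r^2.

    A flat curve (zero total sum of squares) has no meaningful r^2 and is
    reported as NaN rather than 1.
    """
    x = curve.grid_pct
    y = curve.delta_suvr_pct
    if len(np.unique(x)) < 4:
        raise ValueError("cubic fit needs at least 4 distinct grid points")
    coeffs = np.polyfit(x, y, 3)
    resid = y - np.polyval(coeffs, x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = float("nan") if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    curve.cubic_coeffs = coeffs
    curve.r_squared = r2
    return coeffs, r2


def delta_suvr_time_course(
    target_p: KineticParams,
    ref_p: KineticParams,
    input_function: InputFunction,
    mode: Mode,
    dk1_pct: float,
    frames: FrameSchedule = DEFAULT_FRAME_SCHEDULE,
    cumulative: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """dSUVR as a function of uptake time for one flow change.

    Returns (frame midpoints, dSUVR %). With ``cumulative=False`` each frame
    is its own SUVR window (instantaneous read-out); with ``cumulative=True``
    the window grows from the first frame start to each frame end.
    """
    base_target = simulate_tac(target_p, input_function, frames)
    base_ref = simulate_tac(ref_p, input_function, frames)
    tac_t, tac_r = base_target, base_ref
    if mode in ("target-only", "global"):
        tac_t = simulate_tac(perturb_flow(target_p, dk1_pct), input_function, frames)
    if mode in ("reference-only", "global"):
        tac_r = simulate_tac(perturb_flow(ref_p, dk1_pct), input_function, frames)

    out = np.empty(len(frames))
    t0 = frames.starts[0]
    for i, (start, end) in enumerate(frames.frames):
        window = (t0, end) if cumulative else (start, end)
        try:
            suvr_base = compute_suvr(base_target, base_ref, window)
            suvr_sim = compute_suvr(tac_t, tac_r, window)
        except ValueError:
            # pre-arrival frames carry no reference signal: SUVR undefined
            out[i] = np.nan
            continue
        out[i] = delta_suvr(suvr_sim, suvr_base)
    return frames.midpoints, out
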