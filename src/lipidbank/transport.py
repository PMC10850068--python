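"""Rare-event and transport analyses for bilayer simulations.

Covers lipid flip-flop detection from leaflet traces, water permeation event
counting and permeability, lateral water diffusion, the Tanner-equation
estimate of perpendicular diffusion in a multilamellar stack, Arrhenius
activation energies, and weighted property-binned summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "LeafletTrace",
    "FlipFlopResult",
    "PermeabilityResult",
    "AnisotropyResult",
    "assign_leaflets",
    "detect_flip_flops",
    "flip_flop_rate",
    "count_permeation_events",
    "permeability",
    "lateral_diffusion",
    "perpendicular_diffusion",
    "arrhenius_activation",
    "binned_summary",
    "WATER_CONCENTRATION_NM3",
    "MIDPLANE_CUTOFF_NM",
    "FLIPFLOP_FRAME_CUTOFF",
]

WATER_CONCENTRATION_NM3 = 33.3679  # bulk water concentration, nm^-3
MIDPLANE_CUTOFF_NM = 1.0  # half-width of the midplane buffer zone
FLIPFLOP_FRAME_CUTOFF = 100  # frames after zone entry at which a flip is confirmed

UPPER, LOWER = 1, -1


@dataclass
class LeafletTrace:
    """Leaflet assignment of molecules over time.

    ``labels`` holds the confirmed leaflet per molecule and frame (+1 upper,
    -1 lower); inside the midplane buffer zone the previously confirmed
    label is retained.  ``in_zone`` marks frames spent inside the zone.
    """

    labels: np.ndarray  # (n_molecules, n_frames) int
    in_zone: np.ndarray  # (n_molecules, n_frames) bool
    midplane_z: np.ndarray  # (n_frames,) nm
    cutoff: float = MIDPLANE_CUTOFF_NM


def assign_leaflets(
    headgroup_z: np.ndarray,
    midplane_z: np.ndarray | float = 0.0,
    midplane_cutoff: float = MIDPLANE_CUTOFF_NM,
) -> LeafletTrace:
    """Assign each molecule to a leaflet from its headgroup z coordinate.

    Outside the buffer zone |z - z_mid| >= cutoff the label is the sign of
    (z - z_mid); inside the zone the previous confirmed label is kept, so a
    molecule only changes leaflet after emerging on the other side.  The
    membrane should be centred per frame (midplane = lipid COM z).
    """
    z = np.atleast_2d(np.asarray(headgroup_z, dtype=float))
    n_mol, n_frames = z.shape
    mid = np.broadcast_to(np.asarray(midplane_z, dtype=float), (n_frames,))
    rel = z - mid
    in_zone = np.abs(rel) < midplane_cutoff
    raw = np.where(rel >= 0, UPPER, LOWER)
    labels = raw.copy()
    for m in range(n_mol):
        for f in range(1, n_frames):
            if in_zone[m, f]:
                labels[m, f] = labels[m, f - 1]
    return LeafletTrace(labels=labels, in_zone=in_zone, midplane_z=np.array(mid),
                        cutoff=midplane_cutoff)


@dataclass
class FlipFlopEvent:
    molecule: int
    start_frame: int  # frame of midplane-zone entry
    end_frame: int  # frame at which the opposite leaflet was confirmed


@dataclass
class FlipFlopResult:
    events: list[FlipFlopEvent] = field(default_factory=list)
    rate: float = 0.0  # per molecule per microsecond
    upper_limit: float | None = None  # when no event was observed


def detect_flip_flops(
    trace: LeafletTrace, frame_cutoff: int = FLIPFLOP_FRAME_CUTOFF
) -> list[FlipFlopEvent]:
    """Detect flip-flop events from a leaflet trace.

    A molecule that crossed the midplane buffer zone is confirmed in the new
    leaflet once it has resided there (outside the zone, on the opposite
    side) for ``frame_cutoff`` consecutive frames; each change of the
    confirmed leaflet is one flip-flop event.  Brief excursions shorter than
    the cutoff never change the confirmed leaflet, so neither the excursion
    nor the return counts.  The event count is invariant under z-mirror
    (labels swap) and under time reversal.
    """
    n_mol, n_frames = trace.labels.shape
    if n_frames <= frame_cutoff:
        raise InputError("trace must be longer than the frame cutoff")
    events: list[FlipFlopEvent] = []
    for m in range(n_mol):
        outside = ~trace.in_zone[m]
        sides = trace.labels[m]
        confirmed = 0
        run_side = 0
        run_start = 0
        run_len = 0
        for f in range(n_frames):
            side = sides[f] if outside[f] else 0
            if side == 0 or side != run_side:
                run_side = side
                run_start = f
                run_len = 1 if side != 0 else 0
            else:
                run_len += 1
            if run_side != 0 and run_len >= frame_cutoff and run_side != confirmed:
                if confirmed != 0:
                    events.append(FlipFlopEvent(m, run_start, f))
                confirmed = run_side
    return events


def flip_flop_rate(
    n_events: int, n_molecules: int, analyzed_time_us: float
) -> FlipFlopResult:
    """Flip-flop rate per molecule per microsecond.

    rate = n_events / (n_molecules * time); with zero events the same
    expression with one hypothetical event gives the detection upper limit.
    """
    if analyzed_time_us <= 0 or n_molecules <= 0:
        raise InputError("molecule count and analyzed time must be positive")
    denom = n_molecules * analyzed_time_us
    if n_events == 0:
        return FlipFlopResult(events=[], rate=0.0, upper_limit=1.0 / denom)
    return FlipFlopResult(events=[], rate=n_events / denom, upper_limit=None)


# ---------------------------------------------------------------------------
# water permeation


def count_permeation_events(
    water_z: np.ndarray,
    lower_bound: np.ndarray | float,
    upper_bound: np.ndarray | float,
) -> int:
    """Count complete membrane traversals of water molecules.

    ``water_z`` (n_molecules, n_frames) must be unwrapped along z.  The bulk
    regions lie beyond the membrane slab bounds; a traversal is recorded
    when a molecule that last visited one bulk region reaches the other,
    with the slab in between.  Rebounds (entering the slab and returning to
    the same side) do not count.  The count is invariant under time
    reversal.
    """
    z = np.atleast_2d(np.asarray(water_z, dtype=float))
    n_mol, n_frames = z.shape
    lower = np.broadcast_to(np.asarray(lower_bound, dtype=float), (n_frames,))
    upper = np.broadcast_to(np.asarray(upper_bound, dtype=float), (n_frames,))
    state = np.zeros_like(z, dtype=int)  # -1 lower bulk, 0 slab, +1 upper bulk
    state[z < lower] = -1
    state[z > upper] = 1
    count = 0
    for m in range(n_mol):
        bulk_frames = state[m][state[m] != 0]
        count += int(np.sum(bulk_frames[:-1] != bulk_frames[1:]))
    return count


@dataclass
class PermeabilityResult:
    n_events: int
    r: float  # events per (ns nm^2)
    P: float  # micrometres per second
    c_w: float = WATER_CONCENTRATION_NM3


def permeability(
    n_events: int, time_ns: float, area_nm2: float, c_w: float = WATER_CONCENTRATION_NM3
) -> PermeabilityResult:
    """Water permeability P = r / (2 c_w) from the permeation event rate.

    ``r`` is events per unit time and lateral area (ns^-1 nm^-2), c_w the
    bulk water concentration in nm^-3; the factor 2 accounts for the two
    directions of crossing.  The result is converted from nm/ns to um/s
    (1 nm/ns = 1e6 um/s).
    """
    if time_ns <= 0 or area_nm2 <= 0:
        raise InputError("time and area must be positive")
    r = n_events / (time_ns * area_nm2)
    p_nm_ns = r / (2.0 * c_w)
    return PermeabilityResult(n_events=n_events, r=r, P=p_nm_ns * 1e6, c_w=c_w)


# ---------------------------------------------------------------------------
# diffusion


def _msd(xy: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Mean squared lateral displacement averaged over particles and origins."""
    out = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = xy[:, lag:, :] - xy[:, :-lag, :]
        out[k] = np.mean(np.sum(d**2, axis=2))
    return out


@dataclass
class DiffusionFit:
    D: float  # m^2/s
    r_squared: float
    flagged: bool  # poor linear fit (ballistic or undersampled motion)


def lateral_diffusion(xy: np.ndarray, dt_ns: float) -> DiffusionFit:
    """Lateral diffusion coefficient from the Einstein relation.

    ``xy`` is (n_particles, n_frames, 2) in nm (a single trajectory may be
    passed as (n_frames, 2)).  The MSD is fitted linearly over lags between
    10% and 50% of the trajectory length, avoiding the ballistic and poorly
    sampled regimes, and D = slope / 4.  Fits with R^2 < 0.9 are flagged.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim == 2:
        xy = xy[None, :, :]
    n_frames = xy.shape[1]
    if n_frames < 100:
        raise InputError("at least 100 frames are required for a diffusion fit")
    lags = np.unique(
        np.linspace(max(1, n_frames // 10), n_frames // 2, 60).astype(int)
    )
    msd = _msd(xy, lags)  # nm^2
    if np.allclose(msd, 0.0):  # static particles
        return DiffusionFit(D=0.0, r_squared=1.0, flagged=False)
    tau = lags * dt_ns
    slope, intercept, r, _, _ = stats.linregress(tau, msd)
    d_nm2_ns = max(slope, 0.0) / 4.0
    r2 = float(r**2) if np.std(msd) > 0 else 1.0
    # a straight line fits even a parabola well over a short window, so also
    # compare the slopes of the two window halves to catch ballistic motion
    half = len(lags) // 2
    s1 = stats.linregress(tau[:half], msd[:half]).slope
    s2 = stats.linregress(tau[half:], msd[half:]).slope
    nonlinear = slope <= 0 or (abs(s2 - s1) / slope > 0.5 if slope > 0 else True)
    flagged = r2 < 0.9 or nonlinear
    return DiffusionFit(D=d_nm2_ns * 1e-9, r_squared=r2, flagged=flagged)


@dataclass
class AnisotropyResult:
    D_par: float  # m^2/s
    D_perp: float  # m^2/s
    z_w: float  # nm
    ratio: float  # D_perp / D_par


def perpendicular_diffusion(
    d_par: float, p_um_s: float, z_w_nm: float
) -> AnisotropyResult:
    """Perpendicular water diffusion in a multilamellar stack (Tanner).

    D_perp = D_par * P * z_w / (D_par + P * z_w), the harmonic combination
    of in-plane diffusion and the trans-membrane channel P * z_w, with the
    water layer thickness z_w = box height minus bilayer thickness.  The
    result never exceeds either limiting channel.
    """
    if z_w_nm <= 0:
        raise InputError("water layer thickness must be positive")
    if d_par < 0 or p_um_s < 0:
        raise InputError("transport coefficients must be non-negative")
    pz = p_um_s * 1e-6 * z_w_nm * 1e-9  # m^2/s
    if d_par + pz == 0:
        d_perp = 0.0
    else:
        d_perp = d_par * pz / (d_par + pz)
    ratio = d_perp / d_par if d_par > 0 else 0.0
    return AnisotropyResult(D_par=d_par, D_perp=d_perp, z_w=z_w_nm, ratio=ratio)


REFERENCE_TEMPERATURE_K = 310.0


def arrhenius_activation(
    p_values: Sequence[float],
    temperatures: Sequence[float],
    t_ref: float = REFERENCE_TEMPERATURE_K,
) -> tuple[float, float]:
    """Activation energy from an Arrhenius plot of permeability.

    Least-squares slope of ln(P) versus 1/T gives -E_a / k_B in kelvin; the
    energy is reported in units of k_B * t_ref together with the standard
    error of the slope propagated to the same units.
    """
    p = np.asarray(p_values, dtype=float)
    T = np.asarray(temperatures, dtype=float)
    if len(p) < 3:
        raise InputError("at least three temperatures are required")
    if np.any(p <= 0):
        raise InputError("permeabilities must be positive for an Arrhenius fit")
    fit = stats.linregress(1.0 / T, np.log(p))
    e_a = -fit.slope / t_ref
    err = fit.stderr / t_ref if fit.stderr is not None else 0.0
    return float(e_a), float(err)


def binned_summary(
    values: Sequence[float],
    weights: Sequence[float],
    bin_variable: Sequence[float],
    bins: np.ndarray,
    min_total_weight: float = 0.0,
) -> pd.DataFrame:
    """Weighted mean and SEM of ``values`` binned by ``bin_variable``.

    Weights are typically simulation lengths, so long simulations dominate
    their bin.  The weighted SEM uses the effective sample size
    (sum w)^2 / sum w^2.  Bins whose total weight does not exceed
    ``min_total_weight`` are dropped (e.g. permeation bins with under one
    microsecond of data).
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "weight": np.asarray(weights, dtype=float),
            "x": np.asarray(bin_variable, dtype=float),
        }
    )
    df["bin"] = pd.cut(df["x"], bins=bins)
    rows = []
    for interval, grp in df.groupby("bin", observed=True):
        w = grp["weight"].to_numpy()
        v = grp["value"].to_numpy()
        total = w.sum()
        if len(grp) == 0 or total <= min_total_weight:
            continue
        mean = float(np.average(v, weights=w))
        n_eff = total**2 / np.sum(w**2)
        var = float(np.average((v - mean) ** 2, weights=w))
        sem = float(np.sqrt(var / n_eff)) if n_eff > 1 else np.nan
        rows.append(
            {
                "bin_left": interval.left,
                "bin_right": interval.right,
                "mean": mean,
                "sem": sem,
                "total_weight": total,
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows)
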