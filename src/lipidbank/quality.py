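"""Quality evaluation of simulations against NMR and X-ray experiments.

Order-parameter quality is the probability that a simulated C-H bond order
parameter lies within the experimental error bars, computed from a heavy
tailed one-degree-of-freedom Student's t (Cauchy) distribution of the
standardised deviation.  Per-bond probabilities are averaged into fragment
qualities (sn-1, sn-2, headgroup, total), penalised by the fraction of bonds
for which a quality is available, and combined over lipid species with molar
fraction weights.  Form-factor quality compares the location of the first
minimum of |F(q)| after placing the experimental curve on the simulation
scale with a weighted-least-squares coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import t as student_t

from .errors import InputError

__all__ = [
    "BondQuality",
    "FragmentQuality",
    "SystemQuality",
    "FormFactorQuality",
    "QualityReport",
    "bond_quality",
    "fragment_quality",
    "system_quality",
    "scale_experimental_form_factor",
    "form_factor_quality",
    "first_form_factor_minimum",
    "DEFAULT_EXPERIMENTAL_ERROR",
]

DEFAULT_EXPERIMENTAL_ERROR = 0.02  # assumed error of experimental order parameters

ACYL_FRAGMENTS = ("acyl chain sn-1", "acyl chain sn-2")


@dataclass
class BondQuality:
    """Probability that the simulated order parameter lies within the
    experimental error bars; ``excluded`` marks bonds whose simulation error
    exceeds the experimental error (artificially slow dynamics would
    otherwise inflate the probability)."""

    P: float | None
    excluded: bool = False


def bond_quality(
    s_mean: float,
    s: float,
    n: int,
    s_exp: float,
    ds_exp: float = DEFAULT_EXPERIMENTAL_ERROR,
    *,
    dof: int = 1,
) -> BondQuality:
    """Quality of one C-H bond order parameter.

    ``s`` is the variance of the per-lipid order parameter means and ``n``
    the number of lipids; the standard error of the mean is sqrt(s/n).  The
    probability mass of the dof-degree t distribution (dof = 1, i.e. Cauchy,
    by default for numerical robustness far from the mean) inside
    [s_exp - ds_exp, s_exp + ds_exp] around the simulated mean is returned.
    """
    if n < 2:
        raise InputError("at least two lipids are required for a quality estimate")
    if s < 0:
        raise InputError("variance must be non-negative")
    sem = np.sqrt(s) / np.sqrt(n)
    if sem > ds_exp:
        return BondQuality(P=None, excluded=True)
    if sem == 0.0:
        return BondQuality(P=1.0 if abs(s_mean - s_exp) <= ds_exp else 0.0)
    dist = student_t(df=dof)
    upper = (s_exp + ds_exp - s_mean) / sem
    lower = (s_exp - ds_exp - s_mean) / sem
    return BondQuality(P=float(dist.cdf(upper) - dist.cdf(lower)))


@dataclass
class FragmentQuality:
    fragment: str
    P_frag: float
    F_frag: float  # fraction of fragment bonds with available quality


def fragment_quality(
    bond_qualities: Mapping[str, BondQuality | None],
    membership: Mapping[str, str],
    fragment: str,
) -> FragmentQuality | None:
    """Fragment quality P_frag = <P>_frag * F_frag for one lipid.

    ``bond_qualities`` maps bond names to their quality, with ``None`` for
    bonds lacking a matched experimental value; ``membership`` assigns each
    bond to a fragment (from the mapping table).  ``fragment`` may be one of
    the mapping-table fragments or "total" (all bonds of the molecule).
    Bonds that are excluded or experimentally uncovered count against
    F_frag.  Returns None when the fragment has no bonds at all or no
    available quality.
    """
    if fragment == "total":
        bonds = list(membership)
    else:
        bonds = [b for b, frag in membership.items() if frag == fragment]
    if not bonds:
        return None
    available = [
        bond_qualities[b].P
        for b in bonds
        if bond_qualities.get(b) is not None and bond_qualities[b].P is not None
    ]
    if not available:
        return None
    f_frag = len(available) / len(bonds)
    return FragmentQuality(
        fragment=fragment,
        P_frag=float(np.mean(available) * f_frag),
        F_frag=f_frag,
    )


@dataclass
class SystemQuality:
    """Molar-fraction weighted fragment qualities over the scored lipids."""

    P: dict[str, float] = field(default_factory=dict)  # keys: tails/headgroup/total


def system_quality(
    per_lipid: Mapping[str, Mapping[str, float | None]],
    molar_fractions: Mapping[str, float],
) -> SystemQuality:
    """Combine per-lipid fragment qualities into system-level ones.

    ``per_lipid`` maps lipid name -> {fragment -> P_frag} with fragment keys
    among {"sn-1", "sn-2", "headgroup", "total"}.  "tails" is the average of
    all acyl chain qualities of each lipid; the weights are molar fractions
    renormalised over the lipids actually contributing to each fragment.
    """
    out: dict[str, float] = {}
    for target in ("tails", "headgroup", "total"):
        acc = 0.0
        weight = 0.0
        for lipid, frags in per_lipid.items():
            if target == "tails":
                chains = [frags.get(k) for k in ("sn-1", "sn-2")]
                chains = [c for c in chains if c is not None]
                value = float(np.mean(chains)) if chains else None
            else:
                value = frags.get(target)
            if value is None:
                continue
            chi = molar_fractions.get(lipid, 0.0)
            acc += chi * value
            weight += chi
        if weight > 0:
            out[target] = acc / weight
    return SystemQuality(P=out)


# ---------------------------------------------------------------------------
# form factors


def scale_experimental_form_factor(
    F_sim: np.ndarray, F_exp: np.ndarray, dF_exp: np.ndarray
) -> float:
    """Scale factor k_e placing experimental intensities on the simulation scale.

    k_e = [sum |F_s||F_e|/dF^2] / [sum |F_e|^2/dF^2], the weighted
    least-squares solution of |F_s| ~ k |F_e| with experimental errors as
    weights.  All three arrays must share the experimental q grid.
    """
    F_sim = np.abs(np.asarray(F_sim, dtype=float))
    F_exp = np.abs(np.asarray(F_exp, dtype=float))
    dF_exp = np.asarray(dF_exp, dtype=float)
    denom = np.sum(F_exp**2 / dF_exp**2)
    if denom == 0:
        raise InputError("experimental form factor is identically zero")
    return float(np.sum(F_sim * F_exp / dF_exp**2) / denom)


SAVGOL_WINDOW = 31  # points on the resampled grid; the filter needs an odd window
SAVGOL_ORDER = 1
FIRST_MINIMUM_QMIN = 0.1  # 1/A; skip the q -> 0 region
RESAMPLE_DQ = 0.001  # 1/A; grid spacing typical of experimental curves


def first_form_factor_minimum(
    q: np.ndarray,
    F_abs: np.ndarray,
    *,
    q_min: float = FIRST_MINIMUM_QMIN,
    window: int = SAVGOL_WINDOW,
    polyorder: int = SAVGOL_ORDER,
    dq: float = RESAMPLE_DQ,
) -> float | None:
    """Location of the first local minimum of |F| at q > q_min.

    The curve is resampled onto a uniform 0.001 1/A grid (the spacing on
    which experimental form factors are tabulated, and on which the 31-point
    filter window corresponds to a 0.03 1/A smoothing width) and smoothed
    with a Savitzky-Golay filter before scanning for the first strict sign
    change of the finite difference.  The discrete minimum is refined by a
    three-point parabolic fit, which recovers sub-grid accuracy for the
    V-shaped zeros of oscillatory form factors.  Returns None when no local
    minimum exists in range.
    """
    q = np.asarray(q, dtype=float)
    F_abs = np.asarray(F_abs, dtype=float)
    qs = np.arange(q[0], q[-1] + 0.5 * dq, dq)
    Fs = np.interp(qs, q, F_abs)
    if len(qs) < window:
        window = len(qs) if len(qs) % 2 == 1 else len(qs) - 1
    smooth = savgol_filter(Fs, window, polyorder)
    dF = np.diff(smooth)
    for i in range(1, len(dF)):
        if qs[i] <= q_min:
            continue
        if dF[i - 1] < 0 and dF[i] > 0:
            # parabola through (qs[i-1], qs[i], qs[i+1])
            y0, y1, y2 = smooth[i - 1], smooth[i], smooth[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            return float(qs[i] + shift * dq)
    return None


@dataclass
class FormFactorQuality:
    k_e: float
    q_min_sim: float
    q_min_exp: float
    FF_q: float  # |q_min_sim - q_min_exp| * 100


def form_factor_quality(
    q_sim: np.ndarray,
    F_sim: np.ndarray,
    q_exp: np.ndarray,
    F_exp: np.ndarray,
    dF_exp: np.ndarray | None = None,
) -> FormFactorQuality | None:
    """Form-factor quality FF_q from the first-minimum locations.

    The simulated curve is interpolated onto the experimental q grid to
    compute the scale factor k_e, both curves are Savitzky-Golay smoothed,
    and the first local minima of |F| at q > 0.1 1/A are compared:
    FF_q = |q_min_sim - q_min_exp| * 100.  Returns None with no minimum in
    range on either curve.  The measure is independent of any overall
    positive scaling of either curve.
    """
    q_sim = np.asarray(q_sim, dtype=float)
    F_sim = np.abs(np.asarray(F_sim, dtype=float))
    q_exp = np.asarray(q_exp, dtype=float)
    F_exp = np.abs(np.asarray(F_exp, dtype=float))
    if dF_exp is None:
        dF_exp = np.ones_like(q_exp)
    F_sim_on_exp = np.interp(q_exp, q_sim, F_sim)
    k_e = scale_experimental_form_factor(F_sim_on_exp, F_exp, dF_exp)
    q_min_sim = first_form_factor_minimum(q_sim, F_sim)
    q_min_exp = first_form_factor_minimum(q_exp, k_e * F_exp)
    if q_min_sim is None or q_min_exp is None:
        return None
    return FormFactorQuality(
        k_e=k_e,
        q_min_sim=q_min_sim,
        q_min_exp=q_min_exp,
        FF_q=float(abs(q_min_sim - q_min_exp) * 100.0),
    )


@dataclass
class QualityReport:
    """Ranking payload for one simulation."""

    P_sn1: float | None = None
    P_sn2: float | None = None
    P_hg: float | None = None
    P_total: float | None = None
    FF_q: float | None = None
    tau_rel: float | None = None
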