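"""Conformational-sampling convergence of lipids via principal components.

The slowest internal motions of a flexible lipid dominate the first
principal component of its aligned heavy-atom coordinates.  The convergence
time of the conformational distribution scales linearly with the
autocorrelation decay time of the PC1 projection, tau_convergence =
k * tau_autocorrelation with the empirical calibration k = 49, and the
relative equilibration measure tau_rel = tau_convergence / tau_sim flags
undersampled simulations (tau_rel > 1).  Rigid molecules such as sterols are
excluded upstream via a configurable blacklist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InputError

__all__ = [
    "AlignedConformations",
    "EquilibrationReport",
    "align_conformations",
    "principal_components",
    "autocorrelation_decay_time",
    "relative_equilibration",
    "RIGID_MOLECULES",
    "CALIBRATION_K",
]

CALIBRATION_K = 49.0  # tau_convergence / tau_autocorrelation, fixed calibration
RIGID_MOLECULES = frozenset({"CHOL", "DCHOL"})  # excluded from the analysis


@dataclass
class AlignedConformations:
    """Heavy-atom conformations superposed onto their mean structure.

    ``data`` has shape (n_lipids, n_frames, 3 * n_atoms): each row is one
    lipid configuration with translation and rotation removed by optimal
    superposition onto the average structure of the lipid type.
    """

    data: np.ndarray
    mean_structure: np.ndarray  # (n_atoms, 3)

    @property
    def n_lipids(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation matrix minimising RMSD of P (already centred) onto Q."""
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _superpose_all(configs: np.ndarray, reference: np.ndarray) -> np.ndarray:
    ref = reference - reference.mean(axis=0)
    out = np.empty_like(configs)
    for i, conf in enumerate(configs):
        c = conf - conf.mean(axis=0)
        R = _kabsch(c, ref)
        out[i] = c @ R.T
    return out


def align_conformations(configs: np.ndarray) -> AlignedConformations:
    """Superpose lipid configurations onto their average structure.

    ``configs`` has shape (n_lipids, n_frames, n_atoms, 3).  A two-pass
    procedure is used: superpose every configuration onto the mean of the
    raw (centred) configurations, recompute the mean, and superpose again.
    Collinear structures have a degenerate rotational fit and are rejected.
    """
    configs = np.asarray(configs, dtype=float)
    if configs.ndim != 4 or configs.shape[3] != 3:
        raise InputError("configs must have shape (n_lipids, n_frames, n_atoms, 3)")
    n_lipids, n_frames, n_atoms, _ = configs.shape
    if n_lipids * n_frames < 2:
        raise InputError("at least two configurations are required")

    flat = configs.reshape(-1, n_atoms, 3)
    centred = flat - flat.mean(axis=1, keepdims=True)
    mean0 = centred.mean(axis=0)
    if np.linalg.matrix_rank(mean0 - mean0.mean(axis=0), tol=1e-10) < 2:
        raise AlignmentError("mean structure is degenerate (collinear atoms)")

    pass1 = _superpose_all(centred, mean0)
    mean1 = pass1.mean(axis=0)
    pass2 = _superpose_all(centred, mean1)

    data = pass2.reshape(n_lipids, n_frames, 3 * n_atoms)
    return AlignedConformations(data=data, mean_structure=pass2.mean(axis=0))


@dataclass
class PrincipalComponents:
    components: np.ndarray  # (n_components, 3 * n_atoms), descending variance
    variances: np.ndarray  # eigenvalues of the pooled covariance
    pc1_projections: np.ndarray  # (n_lipids, n_frames), centred


def principal_components(aligned: AlignedConformations) -> PrincipalComponents:
    """PCA of aligned heavy-atom coordinates, pooled over all lipids.

    All configurations of the lipid type enter one covariance matrix (the
    lipids sample the same conformational ensemble); the PC1 projection time
    series is returned per lipid for autocorrelation analysis.
    """
    X = aligned.data.reshape(-1, aligned.data.shape[2])
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (Xc.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    proj = (aligned.data - mean) @ evecs[:, 0]
    proj = proj - proj.mean()
    return PrincipalComponents(
        components=evecs.T, variances=np.clip(evals, 0.0, None), pc1_projections=proj
    )


def _acf(series: np.ndarray) -> np.ndarray:
    """Normalised autocorrelation of a 1-D series via FFT."""
    x = series - series.mean()
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[:n].real
    acov /= np.arange(n, 0, -1)
    if acov[0] <= 0:
        return np.ones(n)
    return acov / acov[0]


def autocorrelation_decay_time(
    series: np.ndarray, dt: float
) -> tuple[float, bool]:
    """Decay time of the PC1 autocorrelation, in the time units of ``dt``.

    The normalised autocorrelation function is computed per lipid and
    averaged over lipids; the decay time is the first lag where the averaged
    ACF falls below 1/e, linearly interpolated between lags.  Returns
    ``(tau, converged)``: when the ACF never falls below 1/e, tau is the
    series length and ``converged`` is False.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[1] < 10:
        raise InputError("series must have at least 10 samples")
    if np.allclose(series, series[:, :1]):
        return float(series.shape[1] * dt), False
    acf = np.mean([_acf(s) for s in series], axis=0)
    threshold = 1.0 / np.e
    below = np.flatnonzero(acf < threshold)
    if len(below) == 0:
        return float(series.shape[1] * dt), False
    i = below[0]
    if i == 0:
        return float(dt), True
    # linear interpolation of the crossing between lags i-1 and i
    frac = (acf[i - 1] - threshold) / (acf[i - 1] - acf[i])
    return float((i - 1 + frac) * dt), True


@dataclass
class EquilibrationReport:
    tau_autocorrelation: float  # ns
    tau_convergence: float  # ns
    tau_sim: float  # ns
    tau_rel: float
    k: float = CALIBRATION_K
    converged: bool = True


def relative_equilibration(
    tau_auto: float, tau_sim: float, *, k: float = CALIBRATION_K, converged: bool = True
) -> EquilibrationReport:
    """Relative equilibration tau_rel = k * tau_autocorrelation / tau_sim."""
    if tau_sim <= 0:
        raise InputError("tau_sim must be positive")
    tau_conv = k * tau_auto
    return EquilibrationReport(
        tau_autocorrelation=tau_auto,
        tau_convergence=tau_conv,
        tau_sim=tau_sim,
        tau_rel=tau_conv / tau_sim,
        k=k,
        converged=converged,
    )
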