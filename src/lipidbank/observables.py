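"""Per-simulation membrane observables.

Calculators for the basic quantities extracted from every bilayer
simulation: C-H bond order parameters, electron density profiles and the
X-ray scattering form factor, area per lipid, and bilayer thickness.

Conventions: the membrane normal is the z axis; coordinates, box vectors and
times are carried in nm and ns in the :class:`FrameEnsemble`; density
profiles use Angstrom and e/A^3 (the units X-ray practitioners print).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError, ThicknessUndefinedError

__all__ = [
    "FrameEnsemble",
    "OrderParameterSet",
    "ElectronDensityProfile",
    "FormFactorCurve",
    "order_parameters",
    "electron_density_profile",
    "form_factor",
    "area_per_lipid",
    "bilayer_thickness",
    "BIN_WIDTH_A",
]

NM_TO_A = 10.0
BIN_WIDTH_A = 1.0 / 3.0  # electron density histogram bin width


@dataclass
class FrameEnsemble:
    """Time series of atomic coordinates with per-atom annotations.

    Attributes
    ----------
    coords : (n_frames, n_atoms, 3) float, nm
    box : (n_frames, 3) float, nm — orthorhombic box vectors (Lx, Ly, Lz)
    times : (n_frames,) float, ns
    electron_counts : (n_atoms,) float
    molecule_ids : (n_atoms,) int — molecule instance each atom belongs to
    molecule_names : (n_atoms,) str — universal molecule name per atom
    atom_names : (n_atoms,) str — universal atom name per atom
    masses : optional (n_atoms,) float, amu; electron counts are used for
        centre-of-mass weights when masses are absent
    """

    coords: np.ndarray
    box: np.ndarray
    times: np.ndarray
    electron_counts: np.ndarray
    molecule_ids: np.ndarray
    molecule_names: np.ndarray
    atom_names: np.ndarray
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.electron_counts = np.asarray(self.electron_counts, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids)
        self.molecule_names = np.asarray(self.molecule_names)
        self.atom_names = np.asarray(self.atom_names)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("coords must have shape (n_frames, n_atoms, 3)")
        if np.any(self.electron_counts < 0):
            raise InputError("electron counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_mask(self, molecule_names: Iterable[str]) -> np.ndarray:
        names = set(molecule_names)
        return np.isin(self.molecule_names, list(names))

    def discard_equilibration(self, t_discard_ns: float) -> "FrameEnsemble":
        """Drop frames earlier than ``t_discard_ns`` (user equilibration period)."""
        keep = self.times >= t_discard_ns
        return FrameEnsemble(
            self.coords[keep],
            self.box[keep],
            self.times[keep],
            self.electron_counts,
            self.molecule_ids,
            self.molecule_names,
            self.atom_names,
            self.masses,
        )

    # simple npz round-trip so fixture trajectories can live on disk
    def save_npz(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez_compressed(
            path,
            coords=self.coords,
            box=self.box,
            times=self.times,
            electron_counts=self.electron_counts,
            molecule_ids=self.molecule_ids,
            molecule_names=self.molecule_names.astype(str),
            atom_names=self.atom_names.astype(str),
            **({"masses": self.masses} if self.masses is not None else {}),
        )
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load_npz(cls, path: str | Path) -> "FrameEnsemble":
        data = np.load(path, allow_pickle=False)
        return cls(
            coords=data["coords"],
            box=data["box"],
            times=data["times"],
            electron_counts=data["electron_counts"],
            molecule_ids=data["molecule_ids"],
            molecule_names=data["molecule_names"],
            atom_names=data["atom_names"],
            masses=data["masses"] if "masses" in data else None,
        )

    @classmethod
    def from_mdanalysis(cls, universe, electron_counts, molecule_names, atom_names):
        """Build from an ``MDAnalysis.Universe`` (coordinates in A -> nm)."""
        import MDAnalysis  # noqa: F401  (optional dependency)

        coords, box, times = [], [], []
        for ts in universe.trajectory:
            coords.append(universe.atoms.positions / NM_TO_A)
            box.append(ts.dimensions[:3] / NM_TO_A)
            times.append(ts.time / 1000.0)  # ps -> ns
        return cls(
            coords=np.array(coords),
            box=np.array(box),
            times=np.array(times),
            electron_counts=np.asarray(electron_counts, dtype=float),
            molecule_ids=universe.atoms.resids,
            molecule_names=np.asarray(molecule_names),
            atom_names=np.asarray(atom_names),
            masses=universe.atoms.masses,
        )


# ---------------------------------------------------------------------------
# order parameters


@dataclass
class BondStatistics:
    """Per C-H bond order parameter statistics over lipids."""

    s_mean: float  # mean of per-lipid order parameters
    s_var: float  # variance of per-lipid means
    n: int  # number of lipids

    @property
    def sem(self) -> float:
        return float(np.sqrt(self.s_var) / np.sqrt(self.n))


@dataclass
class OrderParameterSet:
    """Order parameters for one lipid type, keyed by universal bond name."""

    bonds: dict[str, BondStatistics] = field(default_factory=dict)

    def to_json_mapping(self) -> dict:
        # databank layout: arrays [value, error] keyed by atom pair name
        return {name: [b.s_mean, b.sem] for name, b in self.bonds.items()}


def order_parameters(
    traj: FrameEnsemble,
    bonds: Sequence[tuple[str, str]],
    molecule: str,
) -> OrderParameterSet:
    """C-H bond order parameters S_CH = <3 cos^2(theta) - 1>/2.

    ``theta`` is the angle between each C-H bond and the membrane normal (z).
    The ensemble average runs over all frames of each lipid first; the
    reported mean and its standard error are then taken over lipids, so the
    error bar reflects the independence of individual lipids in a fluid
    bilayer.  Explicit hydrogen positions are required.
    """
    mol_mask = traj.molecule_names == molecule
    if not np.any(mol_mask):
        raise InputError(f"no atoms of molecule {molecule!r} in trajectory")
    lipid_ids = np.unique(traj.molecule_ids[mol_mask])
    result = OrderParameterSet()
    for carbon, hydrogen in bonds:
        per_lipid = np.empty(len(lipid_ids))
        for i, lid in enumerate(lipid_ids):
            sel = mol_mask & (traj.molecule_ids == lid)
            c_idx = np.flatnonzero(sel & (traj.atom_names == carbon))
            h_idx = np.flatnonzero(sel & (traj.atom_names == hydrogen))
            if len(c_idx) != 1 or len(h_idx) != 1:
                raise InputError(
                    f"bond ({carbon}, {hydrogen}) not uniquely resolved in "
                    f"molecule instance {lid}; united-atom topologies without "
                    "explicit hydrogens are not supported"
                )
            vec = traj.coords[:, h_idx[0], :] - traj.coords[:, c_idx[0], :]
            norm = np.linalg.norm(vec, axis=1)
            cos2 = (vec[:, 2] / norm) ** 2
            per_lipid[i] = np.mean(1.5 * cos2 - 0.5)
        result.bonds[f"{carbon} {hydrogen}"] = BondStatistics(
            s_mean=float(np.mean(per_lipid)),
            s_var=float(np.var(per_lipid, ddof=1)) if len(per_lipid) > 1 else 0.0,
            n=len(lipid_ids),
        )
    return result


# ---------------------------------------------------------------------------
# electron density and form factor


@dataclass
class ElectronDensityProfile:
    """Electron density across the membrane, in e/A^3 on a uniform z grid (A)."""

    bin_centers: np.ndarray  # A
    rho_total: np.ndarray
    rho_solvent: np.ndarray
    delta_rho: np.ndarray  # total minus bulk-completed solvent

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    def to_json_mapping(self) -> dict:
        return {
            "z": self.bin_centers.tolist(),
            "rho_total": self.rho_total.tolist(),
            "rho_solvent": self.rho_solvent.tolist(),
            "delta_rho": self.delta_rho.tolist(),
        }


@dataclass
class FormFactorCurve:
    """|F(q)| in e/A^2 on an increasing q grid in 1/A."""

    q: np.ndarray
    F_abs: np.ndarray

    def to_json_rows(self) -> list:
        return [[float(q), float(f)] for q, f in zip(self.q, self.F_abs)]


def _center_z(traj: FrameEnsemble, mask: np.ndarray) -> np.ndarray:
    """Per-frame z coordinates re-centred on the selected molecules' COM."""
    weights = traj.masses if traj.masses is not None else traj.electron_counts
    w = weights[mask]
    z = traj.coords[:, :, 2]
    com = (z[:, mask] * w).sum(axis=1) / w.sum()
    return z - com[:, None]


def electron_density_profile(
    traj: FrameEnsemble,
    lipid_selection: Iterable[str],
    solvent_selection: Iterable[str],
    bin_width: float = BIN_WIDTH_A,
) -> ElectronDensityProfile:
    """Electron density profile across the bilayer.

    Every frame is centred on the centre of mass of the lipid molecules; a
    z histogram of atom positions weighted with the electron count of each
    atom is accumulated with a 1/3 A bin width and averaged over frames.  The
    solvent-subtracted contrast ``delta_rho`` uses the solvent profile
    completed to its bulk plateau (estimated from the outer 20% of the box)
    inside the membrane core, so the contrast vanishes in bulk solvent by
    construction.
    """
    lipid_mask = traj.atom_mask(lipid_selection)
    solvent_mask = traj.atom_mask(solvent_selection)
    if not lipid_mask.any():
        raise InputError("empty lipid selection")
    if not solvent_mask.any():
        raise InputError("empty solvent selection")

    z = _center_z(traj, lipid_mask) * NM_TO_A  # A
    box = traj.box * NM_TO_A
    Lz = float(np.mean(box[:, 2]))
    area = float(np.mean(box[:, 0] * box[:, 1]))
    n_bins = max(int(np.round(Lz / bin_width)), 1)
    edges = np.linspace(-Lz / 2.0, Lz / 2.0, n_bins + 1)
    width = edges[1] - edges[0]
    bin_volume = area * width

    # wrap centred coordinates into [-Lz/2, Lz/2)
    zw = (z + Lz / 2.0) % Lz - Lz / 2.0

    def histo(mask: np.ndarray) -> np.ndarray:
        h = np.zeros(n_bins)
        w = traj.electron_counts[mask]
        for f in range(traj.n_frames):
            h += np.histogram(zw[f, mask], bins=edges, weights=w)[0]
        return h / (traj.n_frames * bin_volume)

    rho_total = histo(np.ones(traj.n_atoms, dtype=bool))
    rho_solvent = histo(solvent_mask)

    # bulk plateau from the outer 20% of the box on both sides
    n_edge = max(int(0.1 * n_bins), 1)
    plateau = float(np.mean(np.concatenate([rho_solvent[:n_edge], rho_solvent[-n_edge:]])))
    solvent_completed = np.maximum(rho_solvent, plateau)
    delta = rho_total - solvent_completed

    centers = 0.5 * (edges[:-1] + edges[1:])
    return ElectronDensityProfile(centers, rho_total, rho_solvent, delta)


def form_factor(
    profile: ElectronDensityProfile,
    q_max: float = 1.0,
    dq: float = 0.005,
) -> FormFactorCurve:
    """X-ray scattering form factor |F(q)| of a (possibly asymmetric) bilayer.

    F(q) = | ∫ delta_rho(z) exp(i q z) dz | over the simulation box along the
    membrane normal, evaluated by the midpoint rule on the histogram grid.
    No symmetry is assumed: real and imaginary parts are both integrated.
    """
    q = np.arange(0.0, q_max + 0.5 * dq, dq)
    z = profile.bin_centers
    dz = profile.bin_width
    phase = np.exp(1j * np.outer(q, z))
    F = phase @ profile.delta_rho * dz
    return FormFactorCurve(q, np.abs(F))


# ---------------------------------------------------------------------------
# area per lipid and thickness


def area_per_lipid(traj: FrameEnsemble, n_membrane_molecules: int) -> float:
    """Area per lipid in A^2.

    Twice the time-averaged lateral box area divided by the total number of
    membrane molecules (lipids plus surfactants), i.e. the lateral area per
    molecule in one leaflet — the convention on which the familiar
    42-74 A^2 scale of fluid bilayers is quoted.
    """
    if n_membrane_molecules <= 0:
        raise InputError("number of membrane molecules must be positive")
    area_nm2 = float(np.mean(traj.box[:, 0] * traj.box[:, 1]))
    return 2.0 * area_nm2 * 100.0 / n_membrane_molecules


def bilayer_thickness(
    lipid_profile: np.ndarray,
    water_profile: np.ndarray,
    z: np.ndarray,
) -> float:
    """Bilayer thickness in nm from lipid/water electron-density crossings.

    The thickness is the distance between the two z positions where the lipid
    and water densities intersect, one on each side of the membrane centre,
    located by linear interpolation between histogram bins.  With noisy
    profiles showing several sign changes, the outermost crossing on each
    side is used.  ``z`` is the profile grid in A; the result is in nm.
    """
    lipid_profile = np.asarray(lipid_profile, dtype=float)
    water_profile = np.asarray(water_profile, dtype=float)
    z = np.asarray(z, dtype=float)
    diff = lipid_profile - water_profile
    total = lipid_profile.sum()
    if total <= 0:
        raise ThicknessUndefinedError("lipid profile carries no density")
    center = float((z * lipid_profile).sum() / total)

    sign_change = np.flatnonzero(np.sign(diff[:-1]) * np.sign(diff[1:]) < 0)

    def interpolate(i: int) -> float:
        z0, z1 = z[i], z[i + 1]
        d0, d1 = diff[i], diff[i + 1]
        return z0 + (z1 - z0) * d0 / (d0 - d1)

    # density curves touching exactly on a grid point (skip all-zero plateaus)
    zero = diff == 0.0
    isolated = zero.copy()
    isolated[1:-1] &= ~(zero[:-2] & zero[2:])
    crossings = np.concatenate(
        [[interpolate(i) for i in sign_change], z[isolated]]
    ).astype(float)
    left = crossings[crossings < center]
    right = crossings[crossings >= center]
    if len(left) == 0 or len(right) == 0:
        raise ThicknessUndefinedError(
            "lipid and water densities do not cross on both membrane sides"
        )
    return (right.max() - left.min()) / NM_TO_A
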