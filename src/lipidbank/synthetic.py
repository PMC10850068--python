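"""Seeded synthetic-data generators with analytic ground truth.

Every generator here produces inputs whose target observable is known in
closed form, independently of the calculators it exercises: oriented C-H
bond ensembles with a prescribed order parameter, slab electron-density
profiles with an analytic form factor, scripted leaflet-crossing and
permeation trajectories, Ornstein-Uhlenbeck and Brownian time series, and
linear composition-property tables.  A mini-databank builder assembles these
into a small on-disk tree of entries, mapping files and synthetic
experiments that exercises the full pipeline.  These fixtures are oracles
for the computations, not physically realistic bilayers.

All generators draw from a dedicated pseudo-random stream derived from the
user seed and the generator name, so outputs are bit-reproducible and
adding a fixture never perturbs the others.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .databank import compute_entry_id
from .errors import InputError
from .observables import BIN_WIDTH_A, ElectronDensityProfile, FrameEnsemble

__all__ = [
    "rng_for",
    "angle_for_order_parameter",
    "make_oriented_bond_trajectory",
    "make_slab_profile",
    "slab_form_factor",
    "scripted_z_series",
    "make_flip_flop_series",
    "make_permeation_series",
    "make_ou_series",
    "make_brownian_walkers",
    "make_regression_dataset",
    "make_bilayer_system",
    "make_mini_databank",
    "FIXTURE_BONDS",
    "REGRESSION_TRUTH",
]

CH_BOND_LENGTH_NM = 0.109


def rng_for(seed: int, name: str) -> np.random.Generator:
    """One independent stream per (seed, fixture name)."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def angle_for_order_parameter(s: float) -> float:
    """Polar angle theta with (3 cos^2(theta) - 1)/2 = s."""
    if not -0.5 <= s <= 1.0:
        raise InputError(f"order parameter target {s} outside [-0.5, 1]")
    return float(np.arccos(np.sqrt((2.0 * s + 1.0) / 3.0)))


# universal bond names of the fixture lipid, with fragment labels
FIXTURE_BONDS: dict[tuple[str, str], str] = {
    ("M_G3C1_M", "M_G3C1H1_M"): "headgroup",
    ("M_G1C3_M", "M_G1C3H1_M"): "glycerol backbone",
    ("M_G1C4_M", "M_G1C4H1_M"): "acyl chain sn-1",
    ("M_G2C4_M", "M_G2C4H1_M"): "acyl chain sn-2",
}


def make_oriented_bond_trajectory(
    targets: Mapping[tuple[str, str], float] | float,
    n_lipids: int = 50,
    n_frames: int = 100,
    seed: int = 0,
    *,
    molecule: str = "POPC",
    tilt_noise: float = 0.0,
    dt_ns: float = 1.0,
    box_nm: tuple[float, float, float] = (6.4, 6.4, 10.0),
) -> tuple[FrameEnsemble, list[tuple[str, str]]]:
    """Ensemble of C-H bonds at fixed polar angle with uniform azimuth.

    Each bond is drawn at theta = arccos(sqrt((2 S + 1)/3)) from the z axis,
    which gives exactly the target order parameter S for every configuration
    (azimuth does not enter).  ``tilt_noise`` adds Gaussian jitter to theta
    (radians) to produce nonzero per-lipid spread when a realistic error bar
    is wanted.  A scalar target applies to all fixture bonds.
    """
    if not isinstance(targets, Mapping):
        targets = {bond: float(targets) for bond in FIXTURE_BONDS}
    rng = rng_for(seed, f"oriented-bonds-{molecule}")
    bonds = list(targets)
    n_bonds = len(bonds)
    n_atoms = n_lipids * n_bonds * 2
    coords = np.zeros((n_frames, n_atoms, 3))
    electron_counts = np.empty(n_atoms)
    molecule_ids = np.empty(n_atoms, dtype=int)
    atom_names = np.empty(n_atoms, dtype=object)

    base = rng.uniform(0.0, box_nm[0], size=(n_lipids, n_bonds, 3))
    idx = 0
    for li in range(n_lipids):
        for bi, (carbon, hydrogen) in enumerate(bonds):
            theta = angle_for_order_parameter(targets[(carbon, hydrogen)])
            th = theta + (
                tilt_noise * rng.standard_normal(n_frames) if tilt_noise else 0.0
            )
            phi = rng.uniform(0.0, 2.0 * np.pi, size=n_frames)
            u = np.stack(
                [np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi), np.cos(th) * np.ones_like(phi)],
                axis=1,
            )
            coords[:, idx, :] = base[li, bi]
            coords[:, idx + 1, :] = base[li, bi] + CH_BOND_LENGTH_NM * u
            electron_counts[idx], electron_counts[idx + 1] = 6.0, 1.0
            molecule_ids[idx : idx + 2] = li
            atom_names[idx], atom_names[idx + 1] = carbon, hydrogen
            idx += 2

    traj = FrameEnsemble(
        coords=coords,
        box=np.tile(np.asarray(box_nm, dtype=float), (n_frames, 1)),
        times=np.arange(n_frames) * dt_ns,
        electron_counts=electron_counts,
        molecule_ids=molecule_ids,
        molecule_names=np.full(n_atoms, molecule, dtype=object),
        atom_names=atom_names,
    )
    return traj, bonds


# ---------------------------------------------------------------------------
# slab density / form factor


def slab_form_factor(q: np.ndarray, d: float, contrast: float) -> np.ndarray:
    """Closed-form |F(q)| of a uniform slab of width d and given contrast."""
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(q == 0, contrast * d, 2.0 * contrast * np.sin(q * d / 2.0) / q)
    return np.abs(F)


def make_slab_profile(
    d: float = 40.0,
    contrast: float = 0.1,
    box: float = 100.0,
    bin_width: float = BIN_WIDTH_A,
) -> ElectronDensityProfile:
    """Uniform-contrast slab profile |z| < d/2 on the histogram grid (A).

    The exact form factor of the continuous slab is
    |2 contrast sin(q d / 2) / q| with first zero at q = 2 pi / d.
    """
    if d >= box:
        raise InputError("slab must fit inside the box")
    n_bins = int(np.round(box / bin_width))
    edges = np.linspace(-box / 2.0, box / 2.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    delta = np.where(np.abs(centers) < d / 2.0, contrast, 0.0)
    plateau = 0.333
    solvent = np.where(np.abs(centers) < d / 2.0, 0.0, plateau)
    return ElectronDensityProfile(
        bin_centers=centers,
        rho_total=delta + plateau,
        rho_solvent=solvent,
        delta_rho=delta,
    )


# ---------------------------------------------------------------------------
# scripted event trajectories


def scripted_z_series(segments: Sequence[tuple[float, int]]) -> np.ndarray:
    """Piecewise-constant z series from (value, n_frames) segments."""
    if any(n <= 0 for _, n in segments):
        raise InputError("segment lengths must be positive")
    return np.concatenate([np.full(n, z, dtype=float) for z, n in segments])


def make_flip_flop_series(
    n_events: int,
    dwell_frames: int,
    *,
    z_leaflet: float = 2.0,
    z_zone: float = 0.0,
    lead_frames: int = 150,
) -> np.ndarray:
    """Headgroup z series scripting exactly ``n_events`` leaflet crossings.

    The molecule starts in the upper leaflet, and for each event passes one
    frame through the midplane zone then dwells ``dwell_frames`` in the
    opposite leaflet.  With ``dwell_frames`` below the detector's frame
    cutoff the crossings must not be counted.
    """
    segments: list[tuple[float, int]] = [(z_leaflet, lead_frames)]
    side = 1.0
    for _ in range(n_events):
        segments.append((z_zone, 1))
        side = -side
        segments.append((side * z_leaflet, dwell_frames))
    segments.append((side * z_leaflet, lead_frames))
    return scripted_z_series(segments)


def make_permeation_series(
    n_traversals: int,
    n_rebounds: int,
    *,
    z_bulk: float = 3.0,
    z_slab_edge: float = 2.0,
    dwell: int = 20,
) -> np.ndarray:
    """Water z series with exact numbers of full traversals and rebounds.

    A traversal moves from one bulk region (|z| > slab bounds) through the
    slab to the other; a rebound enters the slab and returns to the same
    side.  Use slab bounds (-z_slab_edge, +z_slab_edge) when counting.
    """
    inside = 0.5 * z_slab_edge
    segments: list[tuple[float, int]] = [(-z_bulk, dwell)]
    side = -1.0
    for _ in range(n_rebounds):
        segments.append((side * inside, dwell))
        segments.append((side * z_bulk, dwell))
    for _ in range(n_traversals):
        segments.append((side * inside, dwell))
        side = -side
        segments.append((side * inside, dwell))
        segments.append((side * z_bulk, dwell))
    return scripted_z_series(segments)


# ---------------------------------------------------------------------------
# stochastic series


def make_ou_series(
    tau: float,
    n: int,
    dt: float,
    seed: int = 0,
    *,
    n_series: int = 1,
    sigma: float = 1.0,
) -> np.ndarray:
    """Ornstein-Uhlenbeck series with exact discrete-time autocorrelation.

    Uses the exact AR(1) discretisation x_{t+1} = a x_t + sigma
    sqrt(1 - a^2) xi with a = exp(-dt / tau), so the stationary ACF is
    exp(-lag / tau) at every lag.  Shape (n_series, n); squeezed to 1-D for
    a single series.
    """
    if tau <= 0 or dt <= 0:
        raise InputError("tau and dt must be positive")
    rng = rng_for(seed, "ou-series")
    a = np.exp(-dt / tau)
    noise = rng.standard_normal((n_series, n))
    x = np.empty((n_series, n))
    x[:, 0] = sigma * noise[:, 0]
    c = sigma * np.sqrt(1.0 - a**2)
    for t in range(1, n):
        x[:, t] = a * x[:, t - 1] + c * noise[:, t]
    return x[0] if n_series == 1 else x


def make_brownian_walkers(
    d_m2_s: float,
    n_steps: int,
    dt_ns: float,
    seed: int = 0,
    *,
    n_walkers: int = 100,
) -> np.ndarray:
    """2-D Brownian trajectories (nm) with lateral diffusion coefficient D.

    Per-axis step variance 2 D dt; returns (n_walkers, n_steps, 2).
    """
    rng = rng_for(seed, "brownian-walkers")
    d_nm2_ns = d_m2_s * 1e9
    std = np.sqrt(2.0 * d_nm2_ns * dt_ns)
    steps = std * rng.standard_normal((n_walkers, n_steps - 1, 2))
    xy = np.zeros((n_walkers, n_steps, 2))
    xy[:, 1:, :] = np.cumsum(steps, axis=1)
    return xy


REGRESSION_TRUTH = {
    "intercept": 64.0,
    "coefficients": {
        "POPC": 0.0,
        "POPE": -8.0,
        "POPG": 2.0,
        "POPS": -5.0,
        "CHOL": -30.0,
        "SM": -10.0,
        "CL": 40.0,
        "PI": 6.0,
    },
}


def make_regression_dataset(
    n: int = 200,
    noise: float = 0.0,
    seed: int = 0,
    *,
    intercept: float | None = None,
    coefficients: Mapping[str, float] | None = None,
    target: str = "apl",
) -> pd.DataFrame:
    """Composition table with a known affine composition-property law.

    Compositions are Dirichlet-distributed molar fractions over the feature
    classes (with the pure single-component systems always included) and the
    target is intercept + sum(coef * fraction) + Gaussian noise.
    """
    from .regression import FEATURE_CLASSES

    rng = rng_for(seed, "regression-dataset")
    intercept = REGRESSION_TRUTH["intercept"] if intercept is None else intercept
    coefficients = REGRESSION_TRUTH["coefficients"] if coefficients is None else coefficients
    k = len(FEATURE_CLASSES)
    fracs = rng.dirichlet(np.ones(k), size=max(n - k, 0))
    fracs = np.vstack([np.eye(k), fracs])[:n]
    coef = np.array([coefficients[c] for c in FEATURE_CLASSES])
    y = intercept + fracs @ coef
    if noise > 0:
        y = y + noise * rng.standard_normal(len(y))
    df = pd.DataFrame(fracs, columns=list(FEATURE_CLASSES))
    df[target] = y
    return df


# ---------------------------------------------------------------------------
# bilayer system for the mini-databank


def make_bilayer_system(
    n_lipids: int = 36,
    n_frames: int = 60,
    seed: int = 0,
    *,
    apl_A2: float = 64.0,
    thickness_nm: float = 4.0,
    box_z_nm: float = 9.0,
    op_targets: Mapping[tuple[str, str], float] | None = None,
    tilt_noise: float = 0.05,
    dt_ns: float = 1.0,
) -> FrameEnsemble:
    """Toy bilayer with known area per lipid, thickness and order parameters.

    Lipids are split between the two leaflets; each lipid carries the fixture
    C-H bond pairs (oriented for the target order parameters), a headgroup
    phosphorus at the membrane surface, and a column of heavy pseudo-atoms
    through its leaflet giving the slab a lipid electron density of about
    0.30 e/A^3.  Pseudo-water particles (10 electrons each) fill the region
    outside the slab at bulk electron density.  The lateral box area is set
    by the requested area per lipid (per-leaflet convention).
    """
    rng = rng_for(seed, "bilayer-system")
    if op_targets is None:
        op_targets = {
            bond: {"headgroup": 0.05, "glycerol backbone": -0.15}.get(frag, 0.18)
            for bond, frag in FIXTURE_BONDS.items()
        }
    area_nm2 = apl_A2 * n_lipids / 2.0 / 100.0
    lx = float(np.sqrt(area_nm2))
    half_t = thickness_nm / 2.0
    bonds = list(op_targets)

    n_chain = 6
    chain_electrons = 40.0
    atoms_per_lipid = 2 * len(bonds) + 1 + n_chain

    n_per_leaflet = n_lipids // 2
    grid = int(np.ceil(np.sqrt(n_per_leaflet)))
    lipid_xy = []
    lipid_leaflet = []
    for li in range(n_lipids):
        leaflet = 1.0 if li < n_per_leaflet else -1.0
        j = li % n_per_leaflet
        lipid_xy.append(((j % grid + 0.5) * lx / grid, (j // grid + 0.5) * lx / grid))
        lipid_leaflet.append(leaflet)

    n_atoms_lipid = n_lipids * atoms_per_lipid
    # water fills the two slabs outside the membrane at ~0.333 e/A^3
    water_volume_nm3 = area_nm2 * (box_z_nm - thickness_nm)
    n_water = int(np.round(water_volume_nm3 * 33.3679))
    n_atoms = n_atoms_lipid + n_water

    coords = np.zeros((n_frames, n_atoms, 3))
    electron_counts = np.zeros(n_atoms)
    molecule_ids = np.zeros(n_atoms, dtype=int)
    molecule_names = np.empty(n_atoms, dtype=object)
    atom_names = np.empty(n_atoms, dtype=object)

    idx = 0
    for li in range(n_lipids):
        x0, y0 = lipid_xy[li]
        leaflet = lipid_leaflet[li]
        jitter = 0.03 * rng.standard_normal((n_frames, 3))
        # headgroup phosphorus at the membrane surface
        coords[:, idx, :] = np.array([x0, y0, leaflet * (half_t - 0.05)]) + jitter
        electron_counts[idx] = 15.0
        molecule_ids[idx] = li
        atom_names[idx] = "M_P_M"
        idx += 1
        # oriented C-H bond pairs near the surface/backbone region
        for bi, (carbon, hydrogen) in enumerate(bonds):
            theta = angle_for_order_parameter(op_targets[(carbon, hydrogen)])
            th = theta + tilt_noise * rng.standard_normal(n_frames)
            phi = rng.uniform(0.0, 2.0 * np.pi, size=n_frames)
            u = np.stack(
                [np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi), np.cos(th)],
                axis=1,
            )
            zc = leaflet * (half_t - 0.3 - 0.25 * bi)
            cpos = np.array([x0, y0, zc]) + 0.02 * rng.standard_normal((n_frames, 3))
            coords[:, idx, :] = cpos
            coords[:, idx + 1, :] = cpos + CH_BOND_LENGTH_NM * leaflet * u
            electron_counts[idx], electron_counts[idx + 1] = 6.0, 1.0
            molecule_ids[idx : idx + 2] = li
            atom_names[idx], atom_names[idx + 1] = carbon, hydrogen
            idx += 2
        # chain pseudo-atoms scattered through the leaflet interior so the
        # lipid slab density is uniform rather than a comb of atom layers
        for ci in range(n_chain):
            zc = leaflet * rng.uniform(0.0, half_t)
            coords[:, idx, :] = np.array([x0, y0, zc]) + 0.05 * rng.standard_normal(
                (n_frames, 3)
            )
            electron_counts[idx] = chain_electrons
            molecule_ids[idx] = li
            atom_names[idx] = f"M_C{ci}_M"
            idx += 1
    molecule_names[:idx] = "POPC"

    # pseudo-water outside the slab
    for wi in range(n_water):
        side = 1.0 if wi % 2 == 0 else -1.0
        z0 = side * rng.uniform(half_t, box_z_nm / 2.0)
        pos = np.array([rng.uniform(0, lx), rng.uniform(0, lx), z0])
        coords[:, idx, :] = pos + 0.04 * rng.standard_normal((n_frames, 3))
        electron_counts[idx] = 10.0
        molecule_ids[idx] = n_lipids + wi
        molecule_names[idx] = "SOL"
        atom_names[idx] = "M_OW_M"
        idx += 1

    return FrameEnsemble(
        coords=coords,
        box=np.tile([lx, lx, box_z_nm], (n_frames, 1)),
        times=np.arange(n_frames) * dt_ns,
        electron_counts=electron_counts,
        molecule_ids=molecule_ids,
        molecule_names=molecule_names,
        atom_names=atom_names,
    )


# ---------------------------------------------------------------------------
# mini-databank tree

_FIXTURE_FF_ATOMS = {
    "M_G3C1_M": "C13",
    "M_G3C1H1_M": "H13A",
    "M_G1C3_M": "C2",
    "M_G1C3H1_M": "H2",
    "M_G1C4_M": "C32",
    "M_G1C4H1_M": "H32",
    "M_G2C4_M": "C22",
    "M_G2C4H1_M": "H22",
}


def _fixture_mapping_yaml() -> str:
    doc = {}
    for (carbon, hydrogen), fragment in FIXTURE_BONDS.items():
        doc[carbon] = {"ATOMNAME": _FIXTURE_FF_ATOMS[carbon], "FRAGMENT": fragment}
        doc[hydrogen] = {"ATOMNAME": _FIXTURE_FF_ATOMS[hydrogen], "FRAGMENT": fragment}
    doc["M_P_M"] = {"ATOMNAME": "P", "FRAGMENT": "headgroup"}
    return yaml.safe_dump(doc, sort_keys=False)


def make_mini_databank(out_dir: str | Path, seed: int = 0, n_entries: int = 3) -> Path:
    """Write a small databank tree exercising the full pipeline.

    Creates ``Simulations/<id>/`` folders with README.yaml metadata and a
    synthetic bilayer trajectory each, a mapping file for the fixture lipid,
    and one synthetic NMR and one synthetic X-ray experiment compatible with
    all entries.  Entries differ in how closely their order parameters match
    the synthetic experiment, so quality ranking has a known outcome.
    """
    out = Path(out_dir)
    (out / "Simulations").mkdir(parents=True, exist_ok=True)
    (out / "experiments").mkdir(exist_ok=True)
    (out / "mapping_files").mkdir(exist_ok=True)

    (out / "mapping_files" / "POPC_fixture.yaml").write_text(_fixture_mapping_yaml())
    (out / "mapping_files" / "SOL_fixture.yaml").write_text(
        yaml.safe_dump({"M_OW_M": {"ATOMNAME": "OW", "FRAGMENT": "other"}})
    )

    # the synthetic "experimental truth"
    exp_targets = {
        bond: {"headgroup": 0.05, "glycerol backbone": -0.15}.get(frag, 0.18)
        for bond, frag in FIXTURE_BONDS.items()
    }
    op_doc = {
        "KIND": "NMR-order-parameters",
        "TEMPERATURE": 310.0,
        "COMPOSITION": {"POPC": 100.0},
        "COUNTERIONS": None,
        "WATER_PER_LIPID": None,
        "OP_DATA": {
            f"{c} {h}": [float(s), 0.02] for (c, h), s in exp_targets.items()
        },
    }
    (out / "experiments" / "POPC_op.yaml").write_text(yaml.safe_dump(op_doc))

    thickness_nm = 4.0
    q = np.round(np.arange(0.02, 1.0001, 0.005), 6)
    f_exp = slab_form_factor(q, d=10.0 * thickness_nm, contrast=0.033)
    ff_doc = {
        "KIND": "X-ray-form-factor",
        "TEMPERATURE": 310.0,
        "COMPOSITION": {"POPC": 100.0},
        "COUNTERIONS": None,
        "WATER_PER_LIPID": None,
        "FF_DATA": [[float(qi), float(fi), 0.01] for qi, fi in zip(q, f_exp)],
    }
    (out / "experiments" / "POPC_ff.yaml").write_text(yaml.safe_dump(ff_doc))

    # per-entry deviation of the order parameters from the experimental truth
    offsets = np.linspace(0.0, 0.06, n_entries)
    for i, offset in enumerate(offsets):
        targets = {bond: s + offset for bond, s in exp_targets.items()}
        traj = make_bilayer_system(seed=seed + i, op_targets=targets,
                                   thickness_nm=thickness_nm)
        trj_bytes = traj.coords[0].tobytes()
        top_bytes = yaml.safe_dump({"entry": i}).encode()
        entry_id = compute_entry_id(trj_bytes, top_bytes)[:16]
        folder = out / "Simulations" / entry_id
        folder.mkdir(parents=True, exist_ok=True)
        traj.save_npz(folder / "trajectory.npz")
        n_water = int(np.sum(traj.molecule_names == "SOL") )
        readme = {
            "ID": entry_id,
            "DOI": f"10.5281/zenodo.synthetic.{i}",
            "TRJ": "trajectory.npz",
            "TPR": "topology.yaml",
            "SOFTWARE": "synthetic",
            "FF": f"fixtureFF{i}",
            "TEMPERATURE": 310.0,
            "TIMELEFTOUT": 0.0,
            "TRJLENGTH": float(traj.times[-1] + 1.0),
            "COMPOSITION": {
                "POPC": {"NAME": "POPC", "MAPPING": "POPC_fixture.yaml", "COUNT": 36},
                "SOL": {"NAME": "TIP3", "MAPPING": "SOL_fixture.yaml", "COUNT": n_water},
            },
        }
        (folder / "README.yaml").write_text(yaml.safe_dump(readme, sort_keys=False))
        (folder / "topology.yaml").write_text(top_bytes.decode())
    return out
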