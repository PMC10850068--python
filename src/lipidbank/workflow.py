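"""End-to-end pipeline over a databank tree.

Walks entry folders (README.yaml plus trajectory), computes the basic
observables and equilibration measure, evaluates quality against the
experiment folder, and ranks entries — writing the databank's JSON artifact
files (``apl.json``, ``thickness.json``, ``FormFactor.json``,
``eq_times.json``, ``[lipid]OrderParameters.json``,
``[lipid]_OrderParameters_quality.json``, ``[lipid]_FragmentQuality.json``,
``system_quality.json``, ``FormFactorQuality.json``) next to each entry.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from . import equilibration as eq
from . import observables as obs
from . import quality as qual
from .databank import (
    ExperimentEntry,
    KNOWN_MOLECULES,
    MappingTable,
    RankingRecord,
    SimulationEntry,
    molar_percentages,
    match_experiments,
    parse_simulation_entry,
    rank_simulations,
    write_json,
)
from .errors import InputError

__all__ = [
    "load_experiments",
    "load_mapping_tables",
    "bonds_from_mapping",
    "analyze_entry",
    "evaluate_entry_quality",
    "rank_directory",
    "run_pipeline",
]

FRAGMENT_KEYS = {
    "acyl chain sn-1": "sn-1",
    "acyl chain sn-2": "sn-2",
    "headgroup": "headgroup",
    "glycerol backbone": "glycerol backbone",
    "other": "other",
}


def load_experiments(directory: str | Path) -> list[ExperimentEntry]:
    """Load experiment YAML files (KIND/TEMPERATURE/COMPOSITION/…) from a folder."""
    out = []
    for path in sorted(Path(directory).glob("*.yaml")):
        doc = yaml.safe_load(path.read_text())
        counterions = doc.get("COUNTERIONS")
        out.append(
            ExperimentEntry(
                kind=doc["KIND"],
                composition_fractions={
                    str(k): float(v) for k, v in (doc.get("COMPOSITION") or {}).items()
                },
                temperature=float(doc["TEMPERATURE"]),
                counterions=tuple(sorted(counterions)) if counterions else None,
                water_per_lipid=(
                    float(doc["WATER_PER_LIPID"])
                    if doc.get("WATER_PER_LIPID") is not None
                    else None
                ),
                op_data={
                    str(k): (float(v[0]), float(v[1]))
                    for k, v in (doc.get("OP_DATA") or {}).items()
                },
                ff_data=[tuple(map(float, row)) for row in (doc.get("FF_DATA") or [])],
            )
        )
    return out


def load_mapping_tables(directory: str | Path) -> dict[str, MappingTable]:
    tables = {}
    for path in sorted(Path(directory).glob("*.yaml")):
        tables[path.name] = MappingTable.from_yaml(path.name, path.read_text())
    return tables


def bonds_from_mapping(table: MappingTable) -> list[tuple[str, str]]:
    """C-H bonds implied by the universal naming convention.

    The hydrogen of carbon ``M_X_M`` is named ``M_XH1_M``; every carbon row
    with such a partner in the table forms one bond.
    """
    names = {row.universal_atom for row in table.rows}
    bonds = []
    for row in table.rows:
        u = row.universal_atom
        if u.endswith("_M") and "H" not in u[2:-2]:
            partner = u[:-2] + "H1_M"
            if partner in names:
                bonds.append((u, partner))
    return bonds


def _lipid_names(entry: SimulationEntry) -> list[str]:
    return [
        n
        for n in entry.composition
        if KNOWN_MOLECULES[n]["category"] in ("lipid", "sterol", "surfactant")
    ]


def _load_entry(entry_dir: Path) -> tuple[SimulationEntry, obs.FrameEnsemble]:
    entry = parse_simulation_entry((entry_dir / "README.yaml").read_text())
    traj = obs.FrameEnsemble.load_npz(entry_dir / entry.trajectory_name)
    traj = traj.discard_equilibration(entry.equilibration_discard)
    return entry, traj


def analyze_entry(entry_dir: str | Path, mapping_dir: str | Path) -> dict:
    """Compute and store the basic observables for one entry folder."""
    entry_dir = Path(entry_dir)
    entry, traj = _load_entry(entry_dir)
    tables = load_mapping_tables(mapping_dir)
    results: dict = {}

    apl = obs.area_per_lipid(traj, entry.n_membrane_molecules)
    write_json(entry_dir / "apl.json", apl)
    results["apl"] = apl

    lipids = _lipid_names(entry)
    solvent = [n for n in entry.composition if KNOWN_MOLECULES[n]["category"] == "water"]
    profile = obs.electron_density_profile(traj, lipids, solvent)
    thickness = obs.bilayer_thickness(
        profile.rho_total - profile.rho_solvent, profile.rho_solvent, profile.bin_centers
    )
    write_json(entry_dir / "thickness.json", thickness)
    results["thickness"] = thickness

    ff = obs.form_factor(profile)
    write_json(entry_dir / "FormFactor.json", ff.to_json_rows())
    results["form_factor"] = ff

    eq_times: dict[str, float] = {}
    for lipid in lipids:
        table = tables.get(entry.composition[lipid].mapping_table_id)
        if table is None:
            continue
        bonds = bonds_from_mapping(table)
        if bonds:
            ops = obs.order_parameters(traj, bonds, lipid)
            write_json(entry_dir / f"{lipid}OrderParameters.json", ops.to_json_mapping())
            results.setdefault("order_parameters", {})[lipid] = ops
        if lipid not in eq.RIGID_MOLECULES:
            report = _equilibration_for(traj, lipid)
            if report is not None:
                eq_times[lipid] = report.tau_rel
                results.setdefault("equilibration", {})[lipid] = report
    write_json(entry_dir / "eq_times.json", eq_times)
    return results


def _equilibration_for(traj: obs.FrameEnsemble, lipid: str) -> eq.EquilibrationReport | None:
    mask = traj.molecule_names == lipid
    heavy = mask & (traj.electron_counts > 1.5)
    ids = np.unique(traj.molecule_ids[heavy])
    if len(ids) == 0 or traj.n_frames < 10:
        return None
    per_lipid = [traj.coords[:, heavy & (traj.molecule_ids == lid), :] for lid in ids]
    n_heavy = min(c.shape[1] for c in per_lipid)
    configs = np.stack([c[:, :n_heavy, :] for c in per_lipid])  # (n_lipids, n_frames, n_heavy, 3)
    aligned = eq.align_conformations(configs)
    pca = eq.principal_components(aligned)
    dt = float(np.mean(np.diff(traj.times))) if traj.n_frames > 1 else 1.0
    tau_auto, converged = eq.autocorrelation_decay_time(pca.pc1_projections, dt)
    tau_sim = float(traj.times[-1] - traj.times[0] + dt)
    return eq.relative_equilibration(tau_auto, tau_sim, converged=converged)


def evaluate_entry_quality(
    entry_dir: str | Path,
    experiments: Iterable[ExperimentEntry],
    mapping_dir: str | Path,
) -> qual.QualityReport:
    """Score one analyzed entry against matching experiments; write artifacts."""
    entry_dir = Path(entry_dir)
    entry, traj = _load_entry(entry_dir)
    tables = load_mapping_tables(mapping_dir)
    matched = match_experiments(entry, list(experiments))
    op_exps = [e for e in matched if e.kind == "NMR-order-parameters"]
    ff_exps = [e for e in matched if e.kind == "X-ray-form-factor"]

    report = qual.QualityReport()
    fractions = molar_percentages(entry)
    per_lipid_frags: dict[str, dict[str, float | None]] = {}

    for lipid in _lipid_names(entry):
        table = tables.get(entry.composition[lipid].mapping_table_id)
        if table is None:
            continue
        bonds = bonds_from_mapping(table)
        if not bonds:
            continue
        ops = obs.order_parameters(traj, bonds, lipid)
        exp_values: dict[str, tuple[float, float]] = {}
        for e in op_exps:
            exp_values.update(e.op_data)
        bond_qualities: dict[str, qual.BondQuality | None] = {}
        membership: dict[str, str] = {}
        for carbon, hydrogen in bonds:
            name = f"{carbon} {hydrogen}"
            membership[name] = FRAGMENT_KEYS[table.by_universal(carbon).fragment]
            stat = ops.bonds[name]
            if name in exp_values:
                s_exp, ds_exp = exp_values[name]
                bond_qualities[name] = qual.bond_quality(
                    stat.s_mean, stat.s_var, stat.n, s_exp, ds_exp
                )
            else:
                bond_qualities[name] = None
        write_json(
            entry_dir / f"{lipid}_OrderParameters_quality.json",
            {
                name: (bq.P if bq is not None else None)
                for name, bq in bond_qualities.items()
            },
        )
        frags: dict[str, float | None] = {}
        for frag in ("sn-1", "sn-2", "headgroup", "total"):
            fq = qual.fragment_quality(bond_qualities, membership, frag)
            frags[frag] = fq.P_frag if fq is not None else None
        write_json(entry_dir / f"{lipid}_FragmentQuality.json", frags)
        per_lipid_frags[lipid] = frags

    if per_lipid_frags:
        scored_fractions = {
            lipid: fractions.get(lipid, 0.0) for lipid in per_lipid_frags
        }
        sysq = qual.system_quality(per_lipid_frags, scored_fractions)
        write_json(entry_dir / "system_quality.json", sysq.P)
        report.P_total = sysq.P.get("total")
        report.P_hg = sysq.P.get("headgroup")
        # ranking keys for single chains use the fraction-weighted averages too
        for key, frag in (("P_sn1", "sn-1"), ("P_sn2", "sn-2")):
            vals = [
                (scored_fractions[lipid], frags[frag])
                for lipid, frags in per_lipid_frags.items()
                if frags.get(frag) is not None
            ]
            if vals:
                w = sum(v[0] for v in vals)
                setattr(report, key, sum(f * p for f, p in vals) / w if w else None)

    if ff_exps:
        lipids = _lipid_names(entry)
        solvent = [
            n for n in entry.composition if KNOWN_MOLECULES[n]["category"] == "water"
        ]
        profile = obs.electron_density_profile(traj, lipids, solvent)
        ff = obs.form_factor(profile)
        exp = ff_exps[0]
        rows = np.asarray(exp.ff_data, dtype=float)
        ffq = qual.form_factor_quality(ff.q, ff.F_abs, rows[:, 0], rows[:, 1], rows[:, 2])
        if ffq is not None:
            write_json(
                entry_dir / "FormFactorQuality.json",
                {
                    "FFq": ffq.FF_q,
                    "k_e": ffq.k_e,
                    "q_min_sim": ffq.q_min_sim,
                    "q_min_exp": ffq.q_min_exp,
                },
            )
            report.FF_q = ffq.FF_q

    eq_path = entry_dir / "eq_times.json"
    if eq_path.exists():
        import json

        taus = json.loads(eq_path.read_text())
        if taus:
            report.tau_rel = max(taus.values())
    return report


def rank_directory(
    root: str | Path, sort_key: str, *, write: bool = True
) -> list[RankingRecord]:
    """Rank all analyzed entries under ``root/Simulations`` by a quality key."""
    import json

    root = Path(root)
    reports = []
    for entry_dir in sorted((root / "Simulations").iterdir()):
        sq = entry_dir / "system_quality.json"
        eqf = entry_dir / "eq_times.json"
        if not sq.exists() or not eqf.exists():
            continue
        sys_p = json.loads(sq.read_text())
        taus = json.loads(eqf.read_text())
        ffq_file = entry_dir / "FormFactorQuality.json"
        ffq = json.loads(ffq_file.read_text())["FFq"] if ffq_file.exists() else None
        frag_files = sorted(entry_dir.glob("*_FragmentQuality.json"))
        frags = json.loads(frag_files[0].read_text()) if frag_files else {}
        reports.append(
            (
                entry_dir.name,
                {
                    "P_sn1": frags.get("sn-1"),
                    "P_sn2": frags.get("sn-2"),
                    "P_hg": sys_p.get("headgroup"),
                    "P_total": sys_p.get("total"),
                    "FF_q": ffq,
                    "tau_rel": max(taus.values()) if taus else None,
                },
            )
        )
    records = rank_simulations(reports, sort_key)
    if write:
        write_json(
            root / "Ranking" / f"ranking_{sort_key}.json",
            [
                {
                    "entry_id": r.entry_id,
                    "sort_key": r.sort_key,
                    "value": r.value,
                    "tau_rel": r.tau_rel,
                }
                for r in records
            ],
        )
    return records


def run_pipeline(root: str | Path, sort_key: str = "P_sn1") -> list[RankingRecord]:
    """validate -> analyze -> quality -> rank over a mini-databank tree."""
    root = Path(root)
    mapping_dir = root / "mapping_files"
    experiments = load_experiments(root / "experiments")
    for entry_dir in sorted((root / "Simulations").iterdir()):
        if not (entry_dir / "README.yaml").exists():
            continue
        analyze_entry(entry_dir, mapping_dir)
        evaluate_entry_quality(entry_dir, experiments, mapping_dir)
    return rank_directory(root, sort_key)
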