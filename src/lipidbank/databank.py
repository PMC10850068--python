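"""Databank layer: simulation metadata, universal naming, experiment matching, ranking.

The databank keeps one ``README.yaml`` file per simulation.  Each file carries
links to the raw trajectory data, the molecular composition expressed in
universal molecule names, the force-field specific residue names and mapping
tables needed to translate atom names, and the simulation conditions.  This
module parses and validates those files, resolves atoms through mapping
tables, pairs simulations with compatible experimental data sets, and ranks
simulations by their quality scores.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import NamingError, SchemaError, UnmappedAtomError, UsageError, InputError

__all__ = [
    "KNOWN_MOLECULES",
    "WATER_NAMES",
    "ION_NAMES",
    "SimulationEntry",
    "CompositionComponent",
    "MappingTable",
    "MappingRow",
    "ExperimentEntry",
    "RankingRecord",
    "parse_simulation_entry",
    "load_simulation_entries",
    "compute_entry_id",
    "resolve_atom",
    "match_experiments",
    "molar_percentages",
    "rank_simulations",
    "write_json",
]

# Universal molecule names known to the databank, with headgroup charge and a
# coarse category used for the membrane/solvent split.  The registry is
# extensible at run time (``register_molecule``); the entries below cover the
# molecules exercised by the toolkit and its fixtures.
KNOWN_MOLECULES: dict[str, dict] = {
    # phosphatidylcholines
    "POPC": {"category": "lipid", "charge": 0},
    "DPPC": {"category": "lipid", "charge": 0},
    "DMPC": {"category": "lipid", "charge": 0},
    "DOPC": {"category": "lipid", "charge": 0},
    "DLPC": {"category": "lipid", "charge": 0},
    # phosphatidylethanolamines
    "POPE": {"category": "lipid", "charge": 0},
    "DPPE": {"category": "lipid", "charge": 0},
    "DOPE": {"category": "lipid", "charge": 0},
    # anionic lipids
    "POPG": {"category": "lipid", "charge": -1},
    "POPS": {"category": "lipid", "charge": -1},
    "POPI": {"category": "lipid", "charge": -1},
    "SAPI": {"category": "lipid", "charge": -1},
    "TOCL": {"category": "lipid", "charge": -2},
    "TMCL": {"category": "lipid", "charge": -2},
    # sphingolipids and ceramide
    "PSM": {"category": "lipid", "charge": 0},
    "SSM": {"category": "lipid", "charge": 0},
    "CER": {"category": "lipid", "charge": 0},
    # sterols and diacylglycerols
    "CHOL": {"category": "sterol", "charge": 0},
    "DCHOL": {"category": "sterol", "charge": 0},
    "DOG": {"category": "lipid", "charge": 0},
    "SDG": {"category": "lipid", "charge": 0},
    # solvent and ions
    "SOL": {"category": "water", "charge": 0},
    "POT": {"category": "ion", "charge": 1},
    "SOD": {"category": "ion", "charge": 1},
    "LIT": {"category": "ion", "charge": 1},
    "CAL": {"category": "ion", "charge": 2},
    "CES": {"category": "ion", "charge": 1},
    "CLA": {"category": "ion", "charge": -1},
}

WATER_NAMES = frozenset(n for n, m in KNOWN_MOLECULES.items() if m["category"] == "water")
ION_NAMES = frozenset(n for n, m in KNOWN_MOLECULES.items() if m["category"] == "ion")

MEMBRANE_CATEGORIES = frozenset({"lipid", "sterol", "surfactant"})

REQUIRED_KEYS = ("DOI", "TRJ", "TPR", "SOFTWARE", "TEMPERATURE", "COMPOSITION", "TIMELEFTOUT")

FRAGMENTS = ("headgroup", "glycerol backbone", "acyl chain sn-1", "acyl chain sn-2", "other")


def register_molecule(name: str, category: str = "lipid", charge: int = 0) -> None:
    """Add a universal molecule name to the registry."""
    KNOWN_MOLECULES[name] = {"category": category, "charge": charge}


@dataclass
class CompositionComponent:
    """One molecule species of a simulation composition."""

    ff_residue_name: str
    mapping_table_id: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise SchemaError(f"negative molecule count: {self.count}")


@dataclass
class SimulationEntry:
    """Parsed metadata of one simulation (README.yaml dialect)."""

    raw_data_link: str
    trajectory_name: str
    topology_name: str
    software: str
    temperature: float  # K
    composition: dict[str, CompositionComponent]
    equilibration_discard: float  # ns, user-supplied TIMELEFTOUT
    entry_id: str | None = None
    force_field: str | None = None
    trajectory_length: float | None = None  # ns
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise SchemaError(f"temperature must be positive, got {self.temperature}")
        for name in self.composition:
            if name not in KNOWN_MOLECULES:
                raise NamingError(f"unknown universal molecule name: {name!r}")
        if (
            self.trajectory_length is not None
            and self.equilibration_discard >= self.trajectory_length
        ):
            raise SchemaError(
                "equilibration discard "
                f"({self.equilibration_discard} ns) must be shorter than the "
                f"trajectory ({self.trajectory_length} ns)"
            )

    # -- derived quantities -------------------------------------------------

    def counts(self, categories: Iterable[str]) -> int:
        cats = set(categories)
        return sum(
            c.count
            for name, c in self.composition.items()
            if KNOWN_MOLECULES[name]["category"] in cats
        )

    @property
    def n_membrane_molecules(self) -> int:
        return self.counts(MEMBRANE_CATEGORIES)

    @property
    def water_per_lipid(self) -> float | None:
        """Molar water-to-lipid ratio; None when no membrane molecule present."""
        n_mem = self.n_membrane_molecules
        if n_mem == 0:
            return None
        return self.counts({"water"}) / n_mem

    @property
    def counterions(self) -> tuple[str, ...] | None:
        ions = tuple(sorted(n for n in self.composition if n in ION_NAMES))
        return ions or None

    @property
    def charged_lipids(self) -> tuple[str, ...]:
        return tuple(
            sorted(
                n
                for n in self.composition
                if KNOWN_MOLECULES[n]["category"] in MEMBRANE_CATEGORIES
                and KNOWN_MOLECULES[n]["charge"] != 0
            )
        )

    # -- (de)serialization --------------------------------------------------

    def to_mapping(self) -> dict:
        doc = {
            "DOI": self.raw_data_link,
            "TRJ": self.trajectory_name,
            "TPR": self.topology_name,
            "SOFTWARE": self.software,
            "TEMPERATURE": self.temperature,
            "TIMELEFTOUT": self.equilibration_discard,
            "COMPOSITION": {
                name: {
                    "NAME": c.ff_residue_name,
                    "MAPPING": c.mapping_table_id,
                    "COUNT": c.count,
                }
                for name, c in self.composition.items()
            },
        }
        if self.entry_id is not None:
            doc["ID"] = self.entry_id
        if self.force_field is not None:
            doc["FF"] = self.force_field
        if self.trajectory_length is not None:
            doc["TRJLENGTH"] = self.trajectory_length
        doc.update(self.extras)
        return doc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_mapping(), sort_keys=False)


def parse_simulation_entry(yaml_text: str) -> SimulationEntry:
    """Parse a README.yaml document into a :class:`SimulationEntry`.

    Unknown top-level keys are preserved verbatim in ``entry.extras`` so that
    schema evolution in the databank never breaks older readers.
    """
    doc = yaml.safe_load(yaml_text)
    if not isinstance(doc, Mapping):
        raise SchemaError("entry file is not a YAML mapping")
    for key in REQUIRED_KEYS:
        if key not in doc:
            raise SchemaError(f"missing required key: {key}")
    comp_doc = doc["COMPOSITION"]
    if not isinstance(comp_doc, Mapping):
        raise SchemaError("COMPOSITION must be a mapping of universal molecule names")
    composition = {}
    for name, sub in comp_doc.items():
        if not isinstance(sub, Mapping) or not {"NAME", "MAPPING", "COUNT"} <= set(sub):
            raise SchemaError(
                f"composition entry for {name!r} must define NAME, MAPPING and COUNT"
            )
        composition[str(name)] = CompositionComponent(
            ff_residue_name=str(sub["NAME"]),
            mapping_table_id=str(sub["MAPPING"]),
            count=int(sub["COUNT"]),
        )
    known = set(REQUIRED_KEYS) | {"ID", "FF", "TRJLENGTH"}
    extras = {k: v for k, v in doc.items() if k not in known}
    return SimulationEntry(
        raw_data_link=str(doc["DOI"]),
        trajectory_name=str(doc["TRJ"]),
        topology_name=str(doc["TPR"]),
        software=str(doc["SOFTWARE"]),
        temperature=float(doc["TEMPERATURE"]),
        composition=composition,
        equilibration_discard=float(doc["TIMELEFTOUT"]),
        entry_id=str(doc["ID"]) if "ID" in doc else None,
        force_field=str(doc["FF"]) if "FF" in doc else None,
        trajectory_length=float(doc["TRJLENGTH"]) if "TRJLENGTH" in doc else None,
        extras=extras,
    )


def load_simulation_entries(directory: str | Path) -> dict[str, SimulationEntry]:
    """Parse every ``README.yaml`` found below *directory* (entry folders)."""
    directory = Path(directory)
    entries: dict[str, SimulationEntry] = {}
    for readme in sorted(directory.glob("**/README.yaml")):
        entry = parse_simulation_entry(readme.read_text())
        key = entry.entry_id or readme.parent.name
        entries[key] = entry
    return entries


def compute_entry_id(trajectory_bytes: bytes, topology_bytes: bytes) -> str:
    """Deterministic entry identifier from the raw trajectory and topology.

    The identifier is the SHA-256 digest of the topology digest concatenated
    with the trajectory digest, in that fixed order, so the result is
    order-sensitive and collision-resistant.
    """
    if not trajectory_bytes or not topology_bytes:
        raise InputError("trajectory and topology byte streams must be nonempty")
    top = hashlib.sha256(topology_bytes).digest()
    trj = hashlib.sha256(trajectory_bytes).digest()
    return hashlib.sha256(top + trj).hexdigest()


# ---------------------------------------------------------------------------
# mapping tables


@dataclass
class MappingRow:
    universal_atom: str
    ff_atom: str
    fragment: str

    def __post_init__(self) -> None:
        if self.fragment not in FRAGMENTS:
            raise SchemaError(f"unknown fragment label: {self.fragment!r}")


@dataclass
class MappingTable:
    """Force-field atom names → universal atom names with fragment labels."""

    mapping_table_id: str
    rows: list[MappingRow]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.universal_atom in seen:
                raise SchemaError(
                    f"duplicate universal atom {row.universal_atom!r} in "
                    f"mapping table {self.mapping_table_id!r}"
                )
            seen.add(row.universal_atom)

    @classmethod
    def from_mapping(cls, mapping_table_id: str, doc: Mapping) -> "MappingTable":
        """Build from the YAML dialect {universal: {ATOMNAME: .., FRAGMENT: ..}}."""
        rows = [
            MappingRow(
                universal_atom=str(uni),
                ff_atom=str(sub["ATOMNAME"]),
                fragment=str(sub.get("FRAGMENT", "other")),
            )
            for uni, sub in doc.items()
        ]
        return cls(mapping_table_id, rows)

    @classmethod
    def from_yaml(cls, mapping_table_id: str, yaml_text: str) -> "MappingTable":
        return cls.from_mapping(mapping_table_id, yaml.safe_load(yaml_text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                r.universal_atom: {"ATOMNAME": r.ff_atom, "FRAGMENT": r.fragment}
                for r in self.rows
            },
            sort_keys=False,
        )

    def by_ff_atom(self, ff_atom: str) -> MappingRow:
        for row in self.rows:
            if row.ff_atom == ff_atom:
                return row
        raise UnmappedAtomError(
            f"atom {ff_atom!r} not present in mapping table {self.mapping_table_id!r}"
        )

    def by_universal(self, universal_atom: str) -> MappingRow:
        for row in self.rows:
            if row.universal_atom == universal_atom:
                return row
        raise UnmappedAtomError(
            f"universal atom {universal_atom!r} not present in mapping table "
            f"{self.mapping_table_id!r}"
        )


def resolve_atom(
    entry: SimulationEntry,
    molecule: str,
    ff_atom: str,
    tables: Mapping[str, MappingTable],
) -> tuple[str, str]:
    """Translate a force-field atom name to ``(universal_atom, fragment)``."""
    if molecule not in entry.composition:
        raise NamingError(f"molecule {molecule!r} not in entry composition")
    table_id = entry.composition[molecule].mapping_table_id
    if table_id not in tables:
        raise UnmappedAtomError(f"mapping table {table_id!r} not loaded")
    row = tables[table_id].by_ff_atom(ff_atom)
    return row.universal_atom, row.fragment


# ---------------------------------------------------------------------------
# experiment matching


@dataclass
class ExperimentEntry:
    """One experimental data set (NMR order parameters or X-ray form factor)."""

    kind: str  # "NMR-order-parameters" | "X-ray-form-factor"
    composition_fractions: dict[str, float]  # molar percent over membrane molecules
    temperature: float  # K
    counterions: tuple[str, ...] | None = None
    water_per_lipid: float | None = None  # None == fully hydrated
    op_data: dict[str, tuple[float, float]] = field(default_factory=dict)
    ff_data: Sequence[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("NMR-order-parameters", "X-ray-form-factor"):
            raise SchemaError(f"unknown experiment kind: {self.kind!r}")
        for bond, (_, ds) in self.op_data.items():
            if ds <= 0:
                raise SchemaError(f"nonpositive experimental error for {bond!r}")
        qs = [row[0] for row in self.ff_data]
        if any(b <= a for a, b in zip(qs, qs[1:])):
            raise SchemaError("form factor q values must be strictly increasing")


def molar_percentages(entry: SimulationEntry) -> dict[str, float]:
    """Molar percentages over membrane molecules (water and ions excluded)."""
    counts = {
        name: c.count
        for name, c in entry.composition.items()
        if KNOWN_MOLECULES[name]["category"] in MEMBRANE_CATEGORIES
    }
    total = sum(counts.values())
    if total == 0:
        return {}
    return {name: 100.0 * n / total for name, n in counts.items()}


FULL_HYDRATION_RATIO = 25.0  # molar water/lipid above which systems count as fully hydrated


def match_experiments(
    sim: SimulationEntry,
    experiments: Iterable[ExperimentEntry],
    *,
    fraction_tolerance: float = 3.0,  # percentage units
    temperature_tolerance: float = 2.0,  # K
    hydration_threshold: float = FULL_HYDRATION_RATIO,
) -> list[ExperimentEntry]:
    """Select experiments whose conditions are compatible with a simulation.

    A simulation and an experiment match when every membrane molecule's molar
    percentage agrees within ``fraction_tolerance`` percentage units, the
    counterions of charged lipids are identical, and temperatures agree within
    ``temperature_tolerance``.  The hydration level is compared exactly only
    when either side is below ``hydration_threshold`` waters per lipid;
    otherwise both systems count as fully hydrated.
    """
    sim_frac = molar_percentages(sim)
    matched = []
    for exp in experiments:
        names = set(sim_frac) | set(exp.composition_fractions)
        if any(
            abs(sim_frac.get(n, 0.0) - exp.composition_fractions.get(n, 0.0))
            > fraction_tolerance
            for n in names
        ):
            continue
        if abs(sim.temperature - exp.temperature) > temperature_tolerance:
            continue
        if sim.charged_lipids and (sim.counterions or ()) != (exp.counterions or ()):
            continue
        wl_sim = sim.water_per_lipid
        wl_exp = exp.water_per_lipid
        low_sim = wl_sim is not None and wl_sim < hydration_threshold
        low_exp = wl_exp is not None and wl_exp < hydration_threshold
        if low_sim or low_exp:
            a = wl_sim if wl_sim is not None else float("inf")
            b = wl_exp if wl_exp is not None else float("inf")
            if abs(a - b) > 1e-9:
                continue
        matched.append(exp)
    return matched


# ---------------------------------------------------------------------------
# ranking

SORT_KEYS = ("P_sn1", "P_sn2", "P_hg", "P_total", "FF_q")

TAU_REL_DISCARD = 1.3  # simulations with tau_rel above this are not ranked


@dataclass
class RankingRecord:
    entry_id: str
    sort_key: str
    value: float
    tau_rel: float


def _get(report, key: str):
    if isinstance(report, Mapping):
        return report.get(key)
    return getattr(report, key, None)


def rank_simulations(
    reports: Iterable[tuple[str, object]],
    sort_key: str,
    *,
    tau_rel_cutoff: float = TAU_REL_DISCARD,
) -> list[RankingRecord]:
    """Rank simulations by a quality measure, best first.

    Order-parameter qualities sort descending (1 is perfect); the form factor
    quality ``FF_q`` sorts ascending (0 is perfect).  Simulations whose
    slowest lipid degree of freedom has not converged (``tau_rel`` above the
    cutoff) are discarded.  Ties break by entry id for reproducibility.
    """
    if sort_key not in SORT_KEYS:
        raise UsageError(f"unknown sort key {sort_key!r}; expected one of {SORT_KEYS}")
    records = []
    for entry_id, report in reports:
        tau_rel = _get(report, "tau_rel")
        value = _get(report, sort_key)
        if value is None or tau_rel is None:
            raise UsageError(
                f"report for {entry_id!r} lacks {sort_key!r} or tau_rel"
            )
        if tau_rel > tau_rel_cutoff:
            continue
        records.append(RankingRecord(entry_id, sort_key, float(value), float(tau_rel)))
    reverse = sort_key != "FF_q"
    records.sort(
        key=lambda r: ((-r.value if reverse else r.value), r.entry_id)
    )
    return records


def write_json(path: str | Path, obj) -> Path:
    """Write a JSON artifact (databank convention: plain JSON, UTF-8)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))
    return path
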