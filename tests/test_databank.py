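"""Metadata layer: parsing, naming, matching, ranking."""

import pytest
import yaml

from lipidbank import databank as db
from lipidbank.errors import (
    InputError,
    NamingError,
    SchemaError,
    UnmappedAtomError,
    UsageError,
)


def make_entry(**overrides) -> db.SimulationEntry:
    entry = db.parse_simulation_entry(
        yaml.safe_dump(
            {
                "DOI": "10.5281/zenodo.1",
                "TRJ": "t.xtc",
                "TPR": "t.tpr",
                "SOFTWARE": "gromacs",
                "TEMPERATURE": 310.0,
                "TIMELEFTOUT": 0.0,
                "COMPOSITION": {
                    "POPC": {"NAME": "POPC", "MAPPING": "m.yaml", "COUNT": 128},
                    "SOL": {"NAME": "TIP3", "MAPPING": "w.yaml", "COUNT": 5120},
                },
            }
        )
    )
    for k, v in overrides.items():
        object.__setattr__(entry, k, v)
    return entry


class TestParsing:
    def test_minimal_entry_round_trip(self, minimal_entry_yaml):
        entry = db.parse_simulation_entry(minimal_entry_yaml)
        assert entry.composition["POPC"].count == 128
        assert entry.temperature == 310.0
        assert entry.water_per_lipid == 5120 / 128
        again = db.parse_simulation_entry(entry.to_yaml())
        assert again == entry

    @pytest.mark.parametrize("key", db.REQUIRED_KEYS)
    def test_missing_required_key_names_it(self, minimal_entry_yaml, key):
        doc = yaml.safe_load(minimal_entry_yaml)
        del doc[key]
        with pytest.raises(SchemaError, match=key):
            db.parse_simulation_entry(yaml.safe_dump(doc))

    def test_unknown_molecule_rejected(self, minimal_entry_yaml):
        doc = yaml.safe_load(minimal_entry_yaml)
        doc["COMPOSITION"]["XXPC"] = {"NAME": "X", "MAPPING": "m", "COUNT": 1}
        with pytest.raises(NamingError, match="XXPC"):
            db.parse_simulation_entry(yaml.safe_dump(doc))

    def test_unknown_keys_preserved(self, minimal_entry_yaml):
        entry = db.parse_simulation_entry(minimal_entry_yaml + "CUSTOM_KEY: 42\n")
        assert entry.extras["CUSTOM_KEY"] == 42
        assert "CUSTOM_KEY" in entry.to_yaml()

    def test_directory_of_entries(self, tmp_path, minimal_entry_yaml):
        for i in range(4):
            d = tmp_path / f"entry{i}"
            d.mkdir()
            (d / "README.yaml").write_text(minimal_entry_yaml)
        assert len(db.load_simulation_entries(tmp_path)) == 4

    def test_discard_longer_than_trajectory_rejected(self, minimal_entry_yaml):
        doc = yaml.safe_load(minimal_entry_yaml)
        doc["TIMELEFTOUT"] = 600.0
        with pytest.raises(SchemaError):
            db.parse_simulation_entry(yaml.safe_dump(doc))


class TestEntryId:
    def test_deterministic_and_sensitive(self):
        trj, top = b"trajectory-bytes", b"topology-bytes"
        assert db.compute_entry_id(trj, top) == db.compute_entry_id(trj, top)
        flipped = b"trajectory-bytEs"
        assert db.compute_entry_id(flipped, top) != db.compute_entry_id(trj, top)

    def test_order_sensitive(self):
        a, b = b"aaa", b"bbb"
        assert db.compute_entry_id(a, b) != db.compute_entry_id(b, a)

    def test_empty_stream_rejected(self):
        with pytest.raises(InputError):
            db.compute_entry_id(b"", b"x")


class TestMappingTables:
    table = db.MappingTable(
        "m.yaml",
        [
            db.MappingRow("M_G1C3_M", "C2", "acyl chain sn-1"),
            db.MappingRow("M_G1C3H1_M", "H2", "acyl chain sn-1"),
            db.MappingRow("M_P_M", "P", "headgroup"),
        ],
    )

    def test_resolve_atom(self):
        entry = make_entry()
        uni, frag = db.resolve_atom(entry, "POPC", "C2", {"m.yaml": self.table})
        assert (uni, frag) == ("M_G1C3_M", "acyl chain sn-1")

    def test_unknown_atom_errors(self):
        entry = make_entry()
        with pytest.raises(UnmappedAtomError, match="XX"):
            db.resolve_atom(entry, "POPC", "XX", {"m.yaml": self.table})

    def test_all_table_atoms_resolve(self):
        entry = make_entry()
        for row in self.table.rows:
            uni, _ = db.resolve_atom(entry, "POPC", row.ff_atom, {"m.yaml": self.table})
            assert uni == row.universal_atom

    def test_duplicate_universal_name_rejected(self):
        with pytest.raises(SchemaError):
            db.MappingTable(
                "d",
                [
                    db.MappingRow("M_A_M", "A1", "other"),
                    db.MappingRow("M_A_M", "A2", "other"),
                ],
            )


def experiment(temperature=310.0, fractions=None, water_per_lipid=None, counterions=None):
    return db.ExperimentEntry(
        kind="NMR-order-parameters",
        composition_fractions=fractions or {"POPC": 100.0},
        temperature=temperature,
        water_per_lipid=water_per_lipid,
        counterions=counterions,
    )


class TestMatching:
    def test_temperature_window(self):
        sim = make_entry()
        assert db.match_experiments(sim, [experiment(temperature=311.5)])
        assert not db.match_experiments(sim, [experiment(temperature=313.0)])

    def test_composition_window(self):
        sim = make_entry()
        ok = experiment(fractions={"POPC": 97.5, "CHOL": 2.5})
        bad = experiment(fractions={"POPC": 90.0, "CHOL": 10.0})
        assert db.match_experiments(sim, [ok]) == [ok]
        assert db.match_experiments(sim, [bad]) == []

    def test_full_hydration_rule(self):
        # sim at 40 waters per lipid vs experiment at 30: both fully hydrated
        sim = make_entry()
        sim.composition["SOL"].count = 128 * 40
        assert db.match_experiments(sim, [experiment(water_per_lipid=30.0)])
        # below the threshold the hydration level must agree exactly
        sim.composition["SOL"].count = 128 * 10
        assert not db.match_experiments(sim, [experiment(water_per_lipid=30.0)])
        assert db.match_experiments(sim, [experiment(water_per_lipid=10.0)])

    def test_counterions_of_charged_lipids(self):
        sim = db.parse_simulation_entry(
            yaml.safe_dump(
                {
                    "DOI": "x",
                    "TRJ": "t",
                    "TPR": "p",
                    "SOFTWARE": "s",
                    "TEMPERATURE": 310.0,
                    "TIMELEFTOUT": 0.0,
                    "COMPOSITION": {
                        "POPG": {"NAME": "POPG", "MAPPING": "m", "COUNT": 100},
                        "SOD": {"NAME": "NA", "MAPPING": "i", "COUNT": 100},
                        "SOL": {"NAME": "W", "MAPPING": "w", "COUNT": 4000},
                    },
                }
            )
        )
        same = experiment(fractions={"POPG": 100.0}, counterions=("SOD",))
        other = experiment(fractions={"POPG": 100.0}, counterions=("POT",))
        assert db.match_experiments(sim, [same, other]) == [same]

    def test_widening_tolerance_is_monotone(self):
        sim = make_entry()
        exps = [
            experiment(temperature=t, fractions={"POPC": f, "CHOL": 100 - f})
            for t in (308.5, 310.0, 312.5)
            for f in (95.0, 98.0, 100.0)
        ]
        previous: set[int] = set()
        for tol_t, tol_f in [(1.0, 1.0), (2.0, 3.0), (4.0, 6.0), (10.0, 50.0)]:
            got = {
                id(e)
                for e in db.match_experiments(
                    sim, exps, fraction_tolerance=tol_f, temperature_tolerance=tol_t
                )
            }
            assert previous <= got
            previous = got


class TestRanking:
    def reports(self, values, tau=0.5, key="P_sn1"):
        return [
            (f"e{i}", {key: v, "tau_rel": tau if not isinstance(tau, list) else tau[i]})
            for i, v in enumerate(values)
        ]

    def test_descending_for_order_parameter_quality(self):
        records = db.rank_simulations(self.reports([0.9, 0.5, 0.7]), "P_sn1")
        assert [r.value for r in records] == [0.9, 0.7, 0.5]

    def test_tau_rel_filter(self):
        records = db.rank_simulations(
            self.reports([0.9, 0.5, 0.7], tau=[0.5, 0.5, 2.0]), "P_sn1"
        )
        assert [r.entry_id for r in records] == ["e0", "e1"]

    def test_ascending_for_form_factor_quality(self):
        records = db.rank_simulations(self.reports([1.2, 0.0], key="FF_q"), "FF_q")
        assert [r.value for r in records] == [0.0, 1.2]

    def test_output_is_permutation_of_kept_input(self):
        reports = self.reports([0.3, 0.8, 0.1, 0.5], tau=[0.2, 1.4, 0.9, 1.0])
        records = db.rank_simulations(reports, "P_sn1")
        kept = {e for e, r in reports if r["tau_rel"] <= 1.3}
        assert {r.entry_id for r in records} == kept

    def test_ties_break_by_entry_id(self):
        records = db.rank_simulations(self.reports([0.5, 0.5, 0.5]), "P_sn1")
        assert [r.entry_id for r in records] == ["e0", "e1", "e2"]

    def test_unknown_sort_key(self):
        with pytest.raises(UsageError):
            db.rank_simulations(self.reports([0.5]), "P_bogus")
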