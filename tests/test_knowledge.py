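"""Knowledge-base data model: validation, subsetting, default fill, IO."""

import csv
from pathlib import Path

import pytest
from hypothesis import given, settings, strategies as st

import hippoloom as hl
from hippoloom.knowledge import (ConnectionEntry, DEFAULT_CLASS_PROBABILITY,
                                 IzhikevichParams, NeuronType, TableError)


def _write_types(path: Path, rows):
    with open(path / "neuron_types.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "subregion", "polarity", "rank", "laminar_code"])
        w.writerows(rows)


class TestValidation:
    def test_toy_fixture_loads(self, toy_kb):
        assert len(toy_kb.neuron_types) == 4
        assert len(toy_kb.connections) == 12  # all ordered non-self pairs

    def test_rank_out_of_range_names_row(self, tmp_path):
        _write_types(tmp_path, [("A", "DG", "excitatory", 1, "123"),
                                ("B", "DG", "inhibitory", 6, "123")])
        with pytest.raises(TableError, match=r"neuron_types\.csv, row 3"):
            hl.load_knowledge_base(tmp_path)

    def test_missing_column(self, tmp_path):
        with open(tmp_path / "neuron_types.csv", "w", newline="") as fh:
            csv.writer(fh).writerows([["name", "subregion", "polarity", "rank"],
                                      ["A", "DG", "excitatory", 1]])
        with pytest.raises(TableError, match="laminar_code"):
            hl.load_knowledge_base(tmp_path)

    def test_duplicate_type_name(self, tmp_path):
        _write_types(tmp_path, [("A", "DG", "excitatory", 1, "123"),
                                ("A", "CA3", "inhibitory", 2, "0p")])
        with pytest.raises(TableError, match="duplicate type name"):
            hl.load_knowledge_base(tmp_path)

    def test_dangling_reference(self, tmp_path):
        _write_types(tmp_path, [("A", "DG", "excitatory", 1, "123")])
        with open(tmp_path / "census.csv", "w", newline="") as fh:
            csv.writer(fh).writerows([["name", "species", "count"],
                                      ["Ghost", "mouse", 10]])
        with pytest.raises(TableError, match="unknown type 'Ghost'"):
            hl.load_knowledge_base(tmp_path)

    def test_blank_rank_defaults_to_three(self, tmp_path):
        _write_types(tmp_path, [("A", "DG", "excitatory", "", "123")])
        kb = hl.load_knowledge_base(tmp_path)
        assert kb.neuron_types["A"].rank == 3
        assert kb.neuron_types["A"].rank_is_default

    def test_mixed_species_rejected(self, toy_kb):
        kb = hl.make_toy_circuit(0)
        some = next(iter(kb.census))
        kb.census[some] = hl.CensusEntry(some, "rat", 10)
        with pytest.raises(TableError, match="mixed species"):
            kb.validate()

    @pytest.mark.parametrize("code", ["", "4", "12x", "p3"])
    def test_bad_laminar_codes(self, code):
        with pytest.raises(TableError):
            NeuronType("A", "DG", "excitatory", 1, code)

    def test_laminar_code_projection_suffix(self):
        nt = NeuronType("A", "DG", "excitatory", 1, "0123p")
        assert nt.laminar_code.endswith("p")

    def test_izhikevich_voltage_ordering_enforced(self):
        with pytest.raises(TableError, match="Vr < Vt < Vpeak"):
            IzhikevichParams(C=100, k=0.7, Vr=-40, Vt=-60, Vpeak=35,
                             Vmin=-50, a=0.03, b=-2, d=100)

    def test_contacts_below_one_rejected_when_connected(self):
        with pytest.raises(TableError, match="contacts"):
            ConnectionEntry("A", "B", probability=0.1, contacts=0.5)


class TestConnectionClass:
    def test_all_four_classes(self):
        got = {hl.connection_class(a, b)
               for a in ("excitatory", "inhibitory")
               for b in ("excitatory", "inhibitory")}
        assert got == {"EE", "EI", "IE", "II"}

    def test_mapping(self):
        assert hl.connection_class("excitatory", "excitatory") == "EE"
        assert hl.connection_class("inhibitory", "excitatory") == "IE"
        assert hl.connection_class("excitatory", "inhibitory") == "EI"


class TestDefaultFill:
    def test_missing_pairs_get_class_averages(self):
        kb = hl.fill_missing_probabilities(hl.make_incomplete_kb(0.0, seed=3))
        for (pre, post), conn in kb.connections.items():
            cls = hl.connection_class(kb.polarity(pre), kb.polarity(post))
            assert conn.probability == DEFAULT_CLASS_PROBABILITY[cls]
            assert conn.is_default

    def test_measured_rows_unchanged(self, toy_kb):
        kb = hl.make_toy_circuit(0)
        pair = next(iter(kb.connections))
        kb.connections[pair] = ConnectionEntry(pair[0], pair[1], 0.2, 2.0)
        filled = hl.fill_missing_probabilities(kb)
        assert filled.connections[pair].probability == 0.2
        assert not filled.connections[pair].is_default

    def test_complete_over_cartesian_product(self):
        kb = hl.fill_missing_probabilities(hl.make_incomplete_kb(0.4, seed=1))
        names = list(kb.neuron_types)
        assert set(kb.connections) == {(a, b) for a in names for b in names}

    def test_idempotent(self):
        kb = hl.fill_missing_probabilities(hl.make_incomplete_kb(0.3, seed=2))
        again = hl.fill_missing_probabilities(kb)
        assert again.connections == kb.connections

    def test_fill_defaults_completes_everything(self):
        kb = hl.make_incomplete_kb(0.2, seed=5)
        kb.izhikevich.pop(next(iter(kb.izhikevich)))
        kb = hl.fill_defaults(kb)
        names = set(kb.neuron_types)
        assert set(kb.izhikevich) == names
        assert set(kb.synapses) >= set(kb.connections)


class TestSelectTypes:
    def test_identity_filter(self, toy_kb):
        out = hl.select_types(toy_kb, max_rank=5)
        assert out == toy_kb

    def test_subregion_and_rank_filter(self, toy_kb):
        out = hl.select_types(toy_kb, subregions={"DG", "CA3"}, max_rank=1)
        # toy fixture has exactly one rank-1 type per subregion
        assert len(out.neuron_types) == 2
        assert {t.rank for t in out.neuron_types.values()} == {1}

    def test_selection_drops_foreign_connection_rows(self, toy_kb):
        name = next(iter(toy_kb.neuron_types))
        out = hl.select_types(toy_kb, names={name})
        expected = {pr for pr in toy_kb.connections
                    if pr[0] == name and pr[1] == name}
        assert set(out.connections) == expected
        assert set(out.synapses) <= {(name, name)}

    def test_filter_idempotence(self, toy_kb):
        once = hl.select_types(toy_kb, subregions={"DG"}, max_rank=2)
        twice = hl.select_types(once, subregions={"DG"}, max_rank=2)
        assert once == twice

    def test_unknown_name_rejected(self, toy_kb):
        with pytest.raises(TableError, match="unknown type names"):
            hl.select_types(toy_kb, names={"No Such Type"})


class TestRoundTrip:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6),
           completeness=st.floats(0.0, 1.0),
           n_types=st.integers(1, 8))
    def test_export_load_identity(self, tmp_path_factory, seed, completeness,
                                  n_types):
        kb = hl.make_random_kb(hl.FixtureSpec(n_types=n_types, seed=seed,
                                              completeness=completeness))
        dest = tmp_path_factory.mktemp("kb")
        hl.export_knowledge_base(kb, dest)
        assert hl.load_knowledge_base(dest) == kb

    def test_empty_kb_exports_header_only(self, tmp_path):
        paths = hl.export_knowledge_base(hl.KnowledgeBase(), tmp_path)
        for path in paths.values():
            lines = path.read_text().strip().splitlines()
            assert len(lines) == 1

    def test_default_flag_survives_round_trip(self, tmp_path):
        kb = hl.fill_missing_probabilities(hl.make_incomplete_kb(0.0, seed=0))
        hl.export_knowledge_base(kb, tmp_path)
        back = hl.load_knowledge_base(tmp_path)
        assert all(c.is_default for c in back.connections.values())
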