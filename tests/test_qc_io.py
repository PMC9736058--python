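"""QC log parsing, energy tables, input decks and system assembly."""

import numpy as np
import pytest

from pkadirect import fixtures
from pkadirect.core_thermo import EnergyRecord, Role
from pkadirect.errors import (
    ConfigError,
    ParseError,
    ProtocolViolationError,
    SchemaError,
    StoichiometryError,
)
from pkadirect.geometry import Geometry
from pkadirect.qc_io import (
    ProtocolSpec,
    assemble_system,
    canonical_basis,
    parse_qc_output,
    read_energy_table,
    system_from_records,
    validate_minimum,
    write_energy_table,
    write_input_deck,
)


@pytest.fixture
def tri():
    return Geometry(
        elements=("O", "H", "H"),
        coords=np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]]),
    )


class TestParser:
    def test_final_energy_round_trip(self):
        log = fixtures.make_mock_log(-307.123456)
        assert parse_qc_output(log).final_energy == pytest.approx(-307.123456, abs=1e-9)

    def test_last_scf_wins(self):
        log = fixtures.make_mock_log(-307.2, extra_scf_energies=[-307.1])
        assert parse_qc_output(log).final_energy == pytest.approx(-307.2, abs=1e-9)

    def test_frequency_order_preserved(self):
        log = fixtures.make_mock_log(-1.0, frequencies=[-42.1, 55.0, 120.5, 300.0])
        calc = parse_qc_output(log)
        assert calc.frequencies == (-42.1, 55.0, 120.5, 300.0)

    def test_geometry_round_trip(self, tri):
        log = fixtures.make_mock_log(-76.4, geometry=tri)
        parsed = parse_qc_output(log)
        assert parsed.geometry.elements == tri.elements
        np.testing.assert_allclose(parsed.geometry.coords, tri.coords, atol=1e-6)

    def test_convergence_flag(self):
        assert parse_qc_output(fixtures.make_mock_log(-1.0, converged=True)).converged
        assert not parse_qc_output(fixtures.make_mock_log(-1.0, converged=False)).converged

    def test_route_metadata_extracted(self):
        calc = parse_qc_output(fixtures.make_mock_log(-1.0))
        assert calc.route_metadata.functional == "CAM-B3LYP"
        assert calc.route_metadata.basis == "6-311+G(d,p)"
        assert calc.route_metadata.solvation == "SMD"
        assert calc.route_metadata.solvent == "water"

    def test_empty_stream_is_a_parse_error(self):
        with pytest.raises(ParseError):
            parse_qc_output("")

    def test_missing_scf_line_is_a_parse_error(self):
        with pytest.raises(ParseError, match="no SCF energy"):
            parse_qc_output("some text\n Normal termination\n", source="bad.log")

    def test_truncated_geometry_block_reports_position(self, tri):
        log = fixtures.make_mock_log(-1.0, geometry=tri)
        cut = "\n".join(log.splitlines()[:7])  # inside the coordinate table
        with pytest.raises(ParseError, match="truncated"):
            parse_qc_output(cut)

    def test_parser_is_idempotent(self, tri):
        log = fixtures.make_mock_log(-76.4, frequencies=[10.0], geometry=tri)
        a, b = parse_qc_output(log), parse_qc_output(log)
        assert a.final_energy == b.final_energy
        assert a.frequencies == b.frequencies
        np.testing.assert_array_equal(a.geometry.coords, b.geometry.coords)


class TestValidateMinimum:
    @pytest.mark.parametrize(
        "freqs,tol,expected",
        [
            ([12.3, 55.0], 0.0, True),
            ([-42.1, 55.0], 0.0, False),
            ([-42.1, 55.0], 50.0, True),
            ([], 0.0, None),
        ],
    )
    def test_minimum_outcomes(self, freqs, tol, expected):
        calc = parse_qc_output(fixtures.make_mock_log(-1.0, frequencies=freqs))
        assert validate_minimum(calc, tol=tol) is expected


class TestEnergyTable:
    def make_records(self, n=2):
        return [
            EnergyRecord(role=Role.HA, label="phenol", n_waters=n, energy=-308.0123456789),
            EnergyRecord(role=Role.A_MINUS, label="phenolate", n_waters=n, energy=-307.5),
            EnergyRecord(role=Role.OH_MINUS, label="OH-", n_waters=n, energy=-75.9),
            EnergyRecord(role=Role.WATER, label="H2O", n_waters=n, energy=-76.45),
        ]

    @pytest.mark.parametrize("count", [0, 1, 4])
    def test_round_trip(self, tmp_path, count):
        records = self.make_records()[:count]
        path = tmp_path / "e.csv"
        write_energy_table(records, path)
        assert read_energy_table(path) == [
            # source is rewritten on read only when empty; ours is "synthetic"
            r for r in records
        ]

    def test_full_precision_survives(self, tmp_path):
        path = tmp_path / "e.csv"
        write_energy_table(self.make_records(), path)
        back = read_energy_table(path)
        assert back[0].energy == -308.0123456789

    def test_unknown_role_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "label,role,n_waters,energy_hartree,source\nphenol,acid,2,-308.0,x\n"
        )
        with pytest.raises(SchemaError, match="unknown role"):
            read_energy_table(path)

    def test_non_numeric_energy_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "label,role,n_waters,energy_hartree,source\nphenol,HA,2,abc,x\n"
        )
        with pytest.raises(SchemaError, match=":2"):
            read_energy_table(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("label,role,energy_hartree\nphenol,HA,-308.0\n")
        with pytest.raises(SchemaError, match="missing columns"):
            read_energy_table(path)

    def test_system_from_records_missing_role(self):
        with pytest.raises(StoichiometryError, match="missing roles"):
            system_from_records(self.make_records()[:3])


class TestInputDeck:
    def test_route_names_functional_and_solvation(self, tri):
        spec = ProtocolSpec(functional="CAM-B3LYP", solvation="SMD", solvent="water")
        deck = write_input_deck(tri, spec)
        route = deck.splitlines()[0]
        assert "CAM-B3LYP" in route
        assert "scrf=(smd,solvent=water)" in route
        assert "6-311+G(d,p)" in route

    def test_no_solvation_directive_when_none(self, tri):
        deck = write_input_deck(tri, ProtocolSpec(solvation="none"))
        assert "scrf" not in deck

    def test_anion_charge_line(self, tri):
        deck = write_input_deck(tri, ProtocolSpec(charge=-1, multiplicity=1))
        assert "-1 1" in deck.splitlines()

    def test_single_point_has_no_opt(self, tri):
        deck = write_input_deck(tri, ProtocolSpec(), job="single_point")
        assert "opt" not in deck.splitlines()[0]

    def test_unregistered_functional_is_config_error(self):
        with pytest.raises(ConfigError):
            ProtocolSpec(functional="M06-2X")

    def test_unregistered_solvation_is_config_error(self):
        with pytest.raises(ConfigError):
            ProtocolSpec(solvation="COSMO")

    def test_basis_spelling_normalized(self):
        assert canonical_basis("6-311G+dp") == "6-311+G(d,p)"
        assert ProtocolSpec(basis="6-311G+dp").basis == "6-311+G(d,p)"

    def test_deck_parse_coherence(self, tri):
        """A deck's coordinates, fed to the mock-log generator, parse back."""
        deck = write_input_deck(tri, ProtocolSpec())
        log = fixtures.mock_log_from_deck(deck, energy=-76.4)
        parsed = parse_qc_output(log)
        np.testing.assert_allclose(parsed.geometry.coords, tri.coords, atol=1e-6)
        assert parsed.geometry.elements == tri.elements


class TestAssembleSystem:
    def calcs(self, ha_freqs=(12.0,), energies=(-308.0, -307.6, -75.9, -76.45)):
        roles = [Role.HA, Role.A_MINUS, Role.OH_MINUS, Role.WATER]
        freqs = {Role.HA: ha_freqs}
        return {
            r: parse_qc_output(
                fixtures.make_mock_log(e, frequencies=list(freqs.get(r, (10.0,)))),
                source=f"{r.value}.log",
            )
            for r, e in zip(roles, energies)
        }

    def test_valid_assembly(self):
        sysx = assemble_system(self.calcs(), n=2)
        assert sysx.n == 2
        assert sysx.ha.energy == pytest.approx(-308.0)

    def test_imaginary_frequency_is_protocol_violation(self):
        with pytest.raises(ProtocolViolationError, match="HA"):
            assemble_system(self.calcs(ha_freqs=(-42.1, 55.0)), n=2)

    def test_mixed_n_waters_is_stoichiometry_error(self):
        with pytest.raises(StoichiometryError):
            assemble_system(self.calcs(), n=2, n_waters={Role.HA: 1})

    def test_missing_role_rejected(self):
        calcs = self.calcs()
        del calcs[Role.WATER]
        with pytest.raises(StoichiometryError, match="WATER"):
            assemble_system(calcs, n=2)
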