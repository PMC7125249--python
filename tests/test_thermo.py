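"""Partition-function aggregation, solvation energies and log P."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pmvlogp import (
    STANDARD,
    CorrectionParams,
    CoverageError,
    MoleculeEnsemble,
    Phase,
    PhaseError,
    StateRecord,
    ThermoConstants,
    boltzmann_aggregate,
    corrected_chemical_potential,
    correction_preset,
    log_partition_coefficient,
    molecule_gibbs_energy,
    predict_logp_table,
    solvation_free_energy,
    state_gibbs_energy,
    vacuum_gibbs_energy,
)

RT = STANDARD.RT


def _state(mol="M1", taut="t1", conf="c0", phase=Phase.water, E_sol=0.0,
           mu_ex=0.0, V_m=0.0, q=0):
    return StateRecord(
        molecule_id=mol, tautomer_id=taut, conformer_id=conf, phase=phase,
        E_sol=E_sol, mu_ex=mu_ex, V_m=V_m, q=q,
    )


def _vac(mol="M1", taut="t1", conf="v0", E_vac=0.0, q=0):
    return StateRecord(
        molecule_id=mol, tautomer_id=taut, conformer_id=conf,
        phase=Phase.vacuum, E_vac=E_vac, q=q,
    )


class TestCorrectedChemicalPotential:
    @pytest.mark.parametrize(
        "mu,V,q,solvent,model,expected",
        [
            (-10.0, 150.0, 0, "octanol_wet", "2-par", -14.8649),
            (-10.0, 100.0, 0, "water", "2-par", -20.251),
            (0.0, 0.0, 0, "octanol_dry", "1-par", 0.0),
        ],
    )
    def test_linear_correction(self, mu, V, q, solvent, model, expected):
        params = correction_preset(solvent, model)
        assert corrected_chemical_potential(mu, V, q, params) == pytest.approx(
            expected, abs=1e-10
        )

    def test_charge_term(self):
        params = correction_preset("water")
        assert corrected_chemical_potential(0.0, 0.0, 1, params) == pytest.approx(
            -15.728
        )


class TestStateGibbsEnergy:
    def test_sum_of_components(self):
        params = correction_preset("octanol_wet", "2-par")
        rec = _state(phase=Phase.octanol_wet, E_sol=-500.0, mu_ex=-10.0, V_m=150.0)
        assert state_gibbs_energy(rec, params) == pytest.approx(-514.8649, abs=1e-10)

    def test_all_zero(self):
        assert state_gibbs_energy(_state(), CorrectionParams()) == 0.0

    def test_vacuum_record_rejected(self):
        with pytest.raises(PhaseError):
            state_gibbs_energy(_vac(), CorrectionParams())


class TestBoltzmannAggregate:
    def test_single_state_identity(self):
        assert boltzmann_aggregate([5.0]) == pytest.approx(5.0, abs=1e-12)

    def test_two_degenerate_states(self):
        assert boltzmann_aggregate([0.0, 0.0]) == pytest.approx(
            -RT * math.log(2), abs=1e-12
        )
        assert boltzmann_aggregate([0.0, 0.0]) == pytest.approx(-0.41068, abs=1e-5)

    def test_negligible_high_state_is_stable(self):
        assert boltzmann_aggregate([0.0, 100.0]) == pytest.approx(0.0, abs=1e-12)

    def test_huge_absolute_energies_do_not_overflow(self):
        assert boltzmann_aggregate([-1e5, -1e5]) == pytest.approx(
            -1e5 - RT * math.log(2), abs=1e-9
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_aggregate([])

    @given(st.lists(st.floats(-1e4, 1e3, allow_nan=False), min_size=1, max_size=8))
    def test_bounded_by_minimum(self, energies):
        agg = boltzmann_aggregate(energies)
        assert agg <= min(energies) + 1e-12
        if len(energies) == 1:
            assert agg == pytest.approx(energies[0], abs=1e-12)

    @given(
        st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=6),
        st.floats(-1e4, 1e4, allow_nan=False),
    )
    def test_offset_covariance(self, energies, delta):
        shifted = boltzmann_aggregate([e + delta for e in energies])
        assert shifted == pytest.approx(
            boltzmann_aggregate(energies) + delta, rel=1e-12, abs=1e-9
        )

    @given(st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=6))
    def test_matches_naive_summation(self, energies):
        """Stable log-sum-exp equals the direct sum at moderate magnitudes."""
        naive = -RT * math.log(sum(math.exp(-e / RT) for e in energies))
        assert boltzmann_aggregate(energies) == pytest.approx(naive, rel=1e-10)

    def test_monotone_in_added_states(self):
        base = boltzmann_aggregate([1.0, 3.0])
        assert boltzmann_aggregate([1.0, 3.0, 10.0]) <= base

    def test_low_temperature_limit_is_minimum(self):
        cold = ThermoConstants(T=1e-3)
        assert boltzmann_aggregate([2.0, 0.5, 7.0], cold) == pytest.approx(
            0.5, abs=1e-4
        )


class TestMoleculeGibbsEnergy:
    def test_single_state_equals_state_energy(self):
        params = correction_preset("water")
        rec = _state(E_sol=-500.0, mu_ex=-12.0, V_m=180.0)
        ens = MoleculeEnsemble.from_records([rec])
        res = molecule_gibbs_energy(ens, params)
        assert res.G_total == pytest.approx(state_gibbs_energy(rec, params), abs=1e-12)
        assert res.weights_per_tautomer == {"t1": 1.0}

    def test_two_tautomer_weights(self):
        """A 5.16 kcal/mol gap leaves ~2e-4 in the minor tautomer."""
        recs = [
            _state(taut="a", E_sol=0.0),
            _state(taut="b", E_sol=5.16),
        ]
        res = molecule_gibbs_energy(
            MoleculeEnsemble.from_records(recs), CorrectionParams()
        )
        expected = 1.0 / (1.0 + math.exp(-5.16 / RT))
        assert res.weights_per_tautomer["a"] == pytest.approx(expected, abs=1e-12)
        assert res.weights_per_tautomer["a"] == pytest.approx(0.99983, abs=1e-4)
        assert sum(res.weights_per_tautomer.values()) == pytest.approx(1.0, abs=1e-12)
        assert res.G_total <= min(res.G_per_tautomer.values())

    def test_shift_covariance_preserves_weights(self):
        recs = [
            _state(taut="a", conf="c0", E_sol=-1.0),
            _state(taut="a", conf="c1", E_sol=0.5),
            _state(taut="b", conf="c0", E_sol=1.2),
        ]
        params = CorrectionParams()
        base = molecule_gibbs_energy(MoleculeEnsemble.from_records(recs), params)
        delta = 7.5
        shifted_recs = [r.model_copy(update={"E_sol": r.E_sol + delta}) for r in recs]
        shifted = molecule_gibbs_energy(
            MoleculeEnsemble.from_records(shifted_recs), params
        )
        assert shifted.G_total == pytest.approx(base.G_total + delta, abs=1e-9)
        for taut in base.weights_per_tautomer:
            assert shifted.weights_per_tautomer[taut] == pytest.approx(
                base.weights_per_tautomer[taut], abs=1e-12
            )

    def test_charge_term_shifts_all_states_equally(self):
        """For fixed q the c_q term cannot change any Boltzmann weight."""
        recs = [
            _state(taut="a", E_sol=-2.0, mu_ex=-5.0, V_m=100.0, q=1),
            _state(taut="b", E_sol=0.0, mu_ex=-4.0, V_m=110.0, q=1),
        ]
        without = CorrectionParams(c_mu=1.0, c_V=-0.01, c_q=0.0)
        with_cq = CorrectionParams(c_mu=1.0, c_V=-0.01, c_q=-15.0)
        res0 = molecule_gibbs_energy(MoleculeEnsemble.from_records(recs), without)
        res1 = molecule_gibbs_energy(MoleculeEnsemble.from_records(recs), with_cq)
        assert res1.G_total == pytest.approx(res0.G_total - 15.0, abs=1e-9)
        for taut in res0.weights_per_tautomer:
            assert res1.weights_per_tautomer[taut] == pytest.approx(
                res0.weights_per_tautomer[taut], abs=1e-12
            )


class TestVacuumAndSolvation:
    def test_single_vacuum_conformer(self):
        assert vacuum_gibbs_energy([_vac(E_vac=-480.0)]) == pytest.approx(-480.0)

    def test_pooled_degenerate_conformers(self):
        vacs = [_vac(conf="v0", E_vac=-480.0), _vac(conf="v1", E_vac=-480.0)]
        assert vacuum_gibbs_energy(vacs) == pytest.approx(
            -480.0 - RT * math.log(2), abs=1e-9
        )

    def test_vacuum_pools_across_tautomers(self):
        vacs = [
            _vac(taut="a", conf="v0", E_vac=-480.0),
            _vac(taut="b", conf="v0", E_vac=-480.0),
        ]
        assert vacuum_gibbs_energy(vacs) == pytest.approx(
            -480.0 - RT * math.log(2), abs=1e-9
        )

    def test_mixed_phase_rejected(self):
        with pytest.raises(PhaseError):
            vacuum_gibbs_energy([_vac(), _state()])

    def test_solvation_free_energy_subtraction(self):
        params = correction_preset("octanol_wet", "2-par")
        sol = MoleculeEnsemble.from_records(
            [_state(phase=Phase.octanol_wet, E_sol=-500.0, mu_ex=-10.0, V_m=150.0)]
        )
        dg = solvation_free_energy(sol, [_vac(E_vac=-480.0)], params)
        assert dg == pytest.approx(-34.8649, abs=1e-10)

    def test_solvation_zero_when_phases_identical(self):
        sol = MoleculeEnsemble.from_records([_state(E_sol=-480.0)])
        dg = solvation_free_energy(sol, [_vac(E_vac=-480.0)], CorrectionParams())
        assert dg == pytest.approx(0.0, abs=1e-12)

    def test_multi_conformer_matches_explicit_sums(self):
        """Composed operations equal a brute-force evaluation."""
        params = CorrectionParams(c_mu=1.2, c_V=-0.02)
        sols = [
            _state(taut="a", conf=f"c{i}", E_sol=e, mu_ex=m, V_m=v)
            for i, (e, m, v) in enumerate(
                [(-10.0, -5.0, 100.0), (-9.0, -5.5, 101.0), (-8.5, -4.0, 99.0)]
            )
        ]
        vacs = [_vac(conf="v0", E_vac=-1.0), _vac(conf="v1", E_vac=0.3)]
        g = [e + 1.2 * m - 0.02 * v for e, m, v in
             [(-10.0, -5.0, 100.0), (-9.0, -5.5, 101.0), (-8.5, -4.0, 99.0)]]
        expected = (
            -RT * math.log(sum(math.exp(-x / RT) for x in g))
            + RT * math.log(sum(math.exp(-x / RT) for x in (-1.0, 0.3)))
        )
        dg = solvation_free_energy(MoleculeEnsemble.from_records(sols), vacs, params)
        assert dg == pytest.approx(expected, rel=1e-12)

    def test_molecule_mismatch_rejected(self):
        sol = MoleculeEnsemble.from_records([_state(mol="A")])
        with pytest.raises(Exception, match="belong"):
            solvation_free_energy(sol, [_vac(mol="B")], CorrectionParams())


class TestLogP:
    def test_unit_gibbs_difference(self):
        assert log_partition_coefficient(STANDARD.RT_ln10, 0.0) == pytest.approx(1.0)
        assert log_partition_coefficient(1.36424, 0.0) == pytest.approx(1.0, abs=1e-4)

    def test_equal_energies_give_zero(self):
        assert log_partition_coefficient(-300.0, -300.0) == 0.0

    @given(st.floats(-500, 500), st.floats(-500, 500))
    def test_antisymmetric_under_solvent_swap(self, gw, go):
        assert log_partition_coefficient(gw, go) == pytest.approx(
            -log_partition_coefficient(go, gw), abs=1e-12
        )

    def test_linearity_in_water_energy(self):
        base = log_partition_coefficient(1.0, 0.0)
        assert log_partition_coefficient(2.0, 0.0) - base == pytest.approx(
            1.0 / STANDARD.RT_ln10, rel=1e-12
        )


class TestPredictLogPTable:
    def test_two_molecule_composition(self):
        """Table prediction equals manual per-molecule composition."""
        pw = correction_preset("water")
        po = correction_preset("octanol_wet", "2-par")
        wat, octa = [], []
        for mol, e in [("A", -100.0), ("B", -50.0)]:
            wat += [
                _state(mol=mol, taut="t1", conf="c0", E_sol=e, mu_ex=-8.0, V_m=120.0),
                _state(mol=mol, taut="t2", conf="c0", E_sol=e + 2.0, mu_ex=-7.0, V_m=121.0),
            ]
            octa.append(
                _state(mol=mol, phase=Phase.octanol_wet, E_sol=e - 1.0,
                       mu_ex=-12.0, V_m=122.0)
            )
        table = predict_logp_table(wat, octa, pw, po)
        assert table["molecule_id"].tolist() == ["A", "B"]
        for mol in ("A", "B"):
            gw = molecule_gibbs_energy(
                MoleculeEnsemble.from_records(wat, molecule_id=mol), pw
            ).G_total
            go = molecule_gibbs_energy(
                MoleculeEnsemble.from_records(octa, molecule_id=mol), po
            ).G_total
            expected = log_partition_coefficient(gw, go)
            got = float(table.set_index("molecule_id").loc[mol, "logP_pred"])
            assert got == pytest.approx(expected, rel=1e-12)

    def test_hand_set_gibbs_difference(self):
        """A transfer Gibbs energy of 2.72848 kcal/mol is log P = 2.0000."""
        wat = [_state(E_sol=2.72848)]
        octa = [_state(phase=Phase.octanol_wet, E_sol=0.0)]
        table = predict_logp_table(wat, octa, CorrectionParams(), CorrectionParams())
        assert float(table["logP_pred"].iloc[0]) == pytest.approx(2.0, abs=1e-4)

    def test_empty_input_gives_empty_table(self):
        table = predict_logp_table([], [], CorrectionParams(), CorrectionParams())
        assert len(table) == 0

    def test_one_sided_molecule_rejected(self):
        with pytest.raises(CoverageError, match="B"):
            predict_logp_table(
                [_state(mol="A"), _state(mol="B", conf="c1")],
                [_state(mol="A", phase=Phase.octanol_wet)],
                CorrectionParams(),
                CorrectionParams(),
            )
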