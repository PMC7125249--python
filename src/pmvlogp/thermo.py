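"""Gibbs energies and log P from corrected energy components.

The Gibbs energy of one solution-phase state is

    G_tc = E_sol + mu_corr,      mu_corr = c_mu*mu_ex + c_V*V_m + c_q*q,

i.e. the polarized electronic energy plus the corrected excess chemical
potential; rotational/vibrational entropic contributions are ignored.
Conformers c of a tautomer t are combined by a discrete partition function

    G_t = -RT ln sum_c exp(-G_tc / RT)

and tautomers by the analogous sum over t.  The decadic partition
coefficient follows from the transfer Gibbs energy between water and
octanol,

    log P = (G_wat - G_oct) / (RT ln 10),

where gas-phase contributions cancel by the thermodynamic cycle, so
absolute solution-phase Gibbs energies are valid inputs.  All partition
functions are evaluated with max-shifted log-sum-exp: absolute electronic
energies are of order 1e2-1e5 kcal/mol and naive exponentiation overflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from .constants import STANDARD, ThermoConstants
from .datamodel import (
    SOLUTION_PHASES,
    CorrectionParams,
    Phase,
    StateRecord,
)
from .errors import CoverageError, PhaseError, ValidationError


def corrected_chemical_potential(
    mu_ex: float, V_m: float, q: float, params: CorrectionParams
) -> float:
    """Corrected excess chemical potential in kcal/mol.

    Applies the three-term linear correction ``c_mu*mu_ex + c_V*V_m + c_q*q``
    that compensates the known partial-molar-volume-scaling error of
    3D RISM excess chemical potentials.
    """
    return params.c_mu * mu_ex + params.c_V * V_m + params.c_q * q


def state_gibbs_energy(record: StateRecord, params: CorrectionParams) -> float:
    """Gibbs energy of a single solution-phase state: E_sol + mu_corr."""
    if record.phase not in SOLUTION_PHASES:
        raise PhaseError(
            f"state {record.key()} is not a solution-phase state"
        )
    return record.E_sol + corrected_chemical_potential(
        record.mu_ex, record.V_m, record.q, params
    )


def boltzmann_aggregate(
    energies: Iterable[float], constants: ThermoConstants = STANDARD
) -> float:
    """Free energy of a discrete ensemble: -RT ln sum_i exp(-G_i/RT).

    Evaluated via max-shifted log-sum-exp so arbitrarily large absolute
    energies neither overflow nor underflow.  The result is always <= the
    minimum input energy, with equality for a single state.
    """
    values = np.asarray(list(energies), dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty collection of energies")
    if not np.all(np.isfinite(values)):
        raise ValueError("energies must be finite")
    rt = constants.RT
    return float(-rt * logsumexp(-values / rt))


@dataclass(frozen=True)
class MoleculeEnsemble:
    """All states of one molecule in one solution phase, grouped by tautomer."""

    molecule_id: str
    phase: Phase
    states: Mapping[str, Sequence[StateRecord]]

    @classmethod
    def from_records(
        cls,
        records: Iterable[StateRecord],
        molecule_id: Optional[str] = None,
        phase: Optional[Phase] = None,
    ) -> "MoleculeEnsemble":
        """Group a (filtered) record list into an ensemble.

        When ``molecule_id``/``phase`` are given, records are filtered to the
        selection; otherwise all records must already share one molecule and
        one solution phase.
        """
        selected = [
            r
            for r in records
            if (molecule_id is None or r.molecule_id == molecule_id)
            and (phase is None or r.phase == phase)
        ]
        if not selected:
            raise ValueError(
                f"no states for molecule={molecule_id!r}, phase={phase!r}"
            )
        mols = {r.molecule_id for r in selected}
        phases = {r.phase for r in selected}
        charges = {r.q for r in selected}
        if len(mols) != 1 or len(phases) != 1:
            raise ValidationError(
                f"ensemble must cover one molecule in one phase, got {mols} x {phases}"
            )
        if len(charges) != 1:
            raise ValidationError(f"inconsistent net charge within {mols}")
        (the_phase,) = phases
        if the_phase not in SOLUTION_PHASES:
            raise PhaseError("ensemble states must be solution-phase")
        grouped: Dict[str, List[StateRecord]] = {}
        for r in selected:
            grouped.setdefault(r.tautomer_id, []).append(r)
        return cls(molecule_id=mols.pop(), phase=the_phase, states=grouped)


@dataclass(frozen=True)
class GibbsResult:
    """Aggregated Gibbs energy of a molecule with per-tautomer breakdown."""

    G_total: float
    G_per_tautomer: Mapping[str, float] = field(default_factory=dict)
    weights_per_tautomer: Mapping[str, float] = field(default_factory=dict)


def molecule_gibbs_energy(
    ensemble: MoleculeEnsemble,
    params: CorrectionParams,
    constants: ThermoConstants = STANDARD,
) -> GibbsResult:
    """Total Gibbs energy of a molecule in one solvent.

    Conformers are aggregated within each tautomer, tautomers aggregated into
    the total; Boltzmann weights of the tautomers are returned normalized.
    """
    if not ensemble.states:
        raise ValueError(f"empty ensemble for {ensemble.molecule_id}")
    g_taut = {
        taut: boltzmann_aggregate(
            [state_gibbs_energy(r, params) for r in records], constants
        )
        for taut, records in ensemble.states.items()
    }
    names = list(g_taut)
    g_values = np.array([g_taut[n] for n in names])
    g_total = float(-constants.RT * logsumexp(-g_values / constants.RT))
    weights = softmax(-g_values / constants.RT)
    return GibbsResult(
        G_total=g_total,
        G_per_tautomer=g_taut,
        weights_per_tautomer=dict(zip(names, (float(w) for w in weights))),
    )


def vacuum_gibbs_energy(
    vacuum_states: Iterable[StateRecord], constants: ThermoConstants = STANDARD
) -> float:
    """Gas-phase reference energy: -RT ln sum exp(-E_vac/RT).

    All vacuum conformers of all tautomers are pooled into a single
    partition-function sum; the gas-phase conformer set need not match the
    solution-phase one.
    """
    records = list(vacuum_states)
    if not records:
        raise ValueError("no vacuum states supplied")
    for r in records:
        if r.phase is not Phase.vacuum:
            raise PhaseError(f"non-vacuum state {r.key()} in vacuum ensemble")
    return boltzmann_aggregate([r.E_vac for r in records], constants)


def solvation_free_energy(
    solution: MoleculeEnsemble,
    vacuum: Iterable[StateRecord],
    params: CorrectionParams,
    constants: ThermoConstants = STANDARD,
) -> float:
    """Solvation Gibbs energy: aggregated solution G minus gas-phase G."""
    vacuum = list(vacuum)
    for r in vacuum:
        if r.molecule_id != solution.molecule_id:
            raise ValidationError(
                f"vacuum state {r.key()} does not belong to {solution.molecule_id}"
            )
    g_sol = molecule_gibbs_energy(solution, params, constants).G_total
    g_vac = vacuum_gibbs_energy(vacuum, constants)
    return g_sol - g_vac


def log_partition_coefficient(
    G_wat: float, G_oct: float, constants: ThermoConstants = STANDARD
) -> float:
    """Decadic octanol-water partition coefficient from phase Gibbs energies.

    Positive values mean preference for the octanol phase.
    """
    return (G_wat - G_oct) / constants.RT_ln10


def predict_logp_table(
    water_states: Sequence[StateRecord],
    octanol_states: Sequence[StateRecord],
    params_water: CorrectionParams,
    params_octanol: CorrectionParams,
    constants: ThermoConstants = STANDARD,
    detail: bool = False,
):
    """Predict log P for every molecule covered by both phase tables.

    Parameters
    ----------
    water_states, octanol_states : sequences of StateRecord
        Solution-phase component tables; each molecule must appear in both.
    params_water, params_octanol : CorrectionParams
        Correction models for the aqueous and the organic phase.
    detail : bool
        When true, also return a per-(molecule, phase, tautomer) breakdown
        with Gibbs energies and Boltzmann weights.

    Returns
    -------
    pandas.DataFrame
        Columns ``molecule_id, logP_pred``, sorted by molecule; with
        ``detail=True`` a tuple ``(predictions, breakdown)``.
    """
    water_states = [r for r in water_states if r.phase is Phase.water]
    octanol_states = [
        r
        for r in octanol_states
        if r.phase in (Phase.octanol_dry, Phase.octanol_wet)
    ]
    oct_phases = {r.phase for r in octanol_states}
    if len(oct_phases) > 1:
        raise ValidationError(
            "octanol table mixes dry and wet phases; split before predicting"
        )
    wat_ids = {r.molecule_id for r in water_states}
    oct_ids = {r.molecule_id for r in octanol_states}
    only = wat_ids.symmetric_difference(oct_ids)
    if only:
        raise CoverageError(
            "molecule(s) present in one phase only: " + ", ".join(sorted(only))
        )
    rows = []
    breakdown = []
    for mol in sorted(wat_ids):
        results = {}
        for label, states, params in (
            ("water", water_states, params_water),
            ("octanol", octanol_states, params_octanol),
        ):
            ens = MoleculeEnsemble.from_records(states, molecule_id=mol)
            res = molecule_gibbs_energy(ens, params, constants)
            results[label] = res
            if detail:
                for taut, g in res.G_per_tautomer.items():
                    breakdown.append(
                        {
                            "molecule_id": mol,
                            "phase": ens.phase.value,
                            "tautomer_id": taut,
                            "G": g,
                            "weight": res.weights_per_tautomer[taut],
                        }
                    )
        logp = log_partition_coefficient(
            results["water"].G_total, results["octanol"].G_total, constants
        )
        rows.append({"molecule_id": mol, "logP_pred": logp})
    predictions = pd.DataFrame(rows, columns=["molecule_id", "logP_pred"])
    if detail:
        return predictions, pd.DataFrame(
            breakdown,
            columns=["molecule_id", "phase", "tautomer_id", "G", "weight"],
        )
    return predictions
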