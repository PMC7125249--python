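"""Tautomer (microstate) stability analysis.

Given per-tautomer Gibbs energies in one or several solvent environments,
these operations compute relative stabilities (Gibbs energies relative to
the most favorable microstate), Boltzmann populations, the dominant
microstate, and whether the stability ranking changes between solvents.
Conformations whose protonation topology changed during upstream structure
optimization can be reassigned to the correct microstate with an explicit
mapping before aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax

from .constants import STANDARD, ThermoConstants
from .datamodel import CorrectionParams, Phase, ReassignmentMap, StateRecord
from .errors import CoverageError, ValidationError
from .thermo import MoleculeEnsemble, molecule_gibbs_energy


def apply_reassignment(
    records: Sequence[StateRecord], mapping: ReassignmentMap
) -> list[StateRecord]:
    """Move listed conformers to their corrected tautomer label.

    Every entry ``(molecule, conformer, phase) -> tautomer`` rewrites the
    tautomer label of the matching rows; all other rows are untouched.  The
    operation is idempotent.

    Raises
    ------
    ValidationError
        If a target tautomer does not exist for the molecule, or an entry
        matches no row at all.
    """
    tautomers_by_mol: Dict[str, set] = {}
    for r in records:
        tautomers_by_mol.setdefault(r.molecule_id, set()).add(r.tautomer_id)
    for (mol, _conf, _phase), target in mapping.entries.items():
        if target not in tautomers_by_mol.get(mol, set()):
            raise ValidationError(
                f"reassignment targets unknown tautomer {target!r} of {mol!r}"
            )
    matched = set()
    out = []
    for r in records:
        key = (r.molecule_id, r.conformer_id, r.phase)
        if key in mapping.entries:
            matched.add(key)
            out.append(r.model_copy(update={"tautomer_id": mapping.entries[key]}))
        else:
            out.append(r)
    unmatched = set(mapping.entries) - matched
    if unmatched:
        raise ValidationError(
            f"reassignment entries match no state row: {sorted(unmatched)}"
        )
    return out


def relative_tautomer_energies(G_per_tautomer: Mapping[str, float]) -> Dict[str, float]:
    """Shift per-tautomer Gibbs energies so the most stable one is at zero."""
    if not G_per_tautomer:
        raise ValueError("empty tautomer energy map")
    g_min = min(G_per_tautomer.values())
    return {taut: g - g_min for taut, g in G_per_tautomer.items()}


def tautomer_populations(
    G_per_tautomer: Mapping[str, float], constants: ThermoConstants = STANDARD
) -> Dict[str, float]:
    """Boltzmann populations of the tautomers; invariant to additive shifts."""
    if not G_per_tautomer:
        raise ValueError("empty tautomer energy map")
    names = list(G_per_tautomer)
    g = np.array([G_per_tautomer[n] for n in names], dtype=float)
    probs = softmax(-g / constants.RT)
    return dict(zip(names, (float(p) for p in probs)))


def stability_ranking(G_per_tautomer: Mapping[str, float]) -> tuple[str, ...]:
    """Tautomers ordered by increasing Gibbs energy, ties broken by label."""
    return tuple(sorted(G_per_tautomer, key=lambda t: (G_per_tautomer[t], t)))


@dataclass(frozen=True)
class TautomerReport:
    """Stability analysis of one molecule in one solvent/model column."""

    molecule_id: str
    column: str
    relative_energies: Mapping[str, float]
    populations: Mapping[str, float]
    dominant: str

    @property
    def ranking(self) -> tuple[str, ...]:
        return stability_ranking(self.relative_energies)


def analyze_molecule(
    records: Iterable[StateRecord],
    params: CorrectionParams,
    molecule_id: Optional[str] = None,
    phase: Optional[Phase] = None,
    constants: ThermoConstants = STANDARD,
    column: Optional[str] = None,
) -> TautomerReport:
    """Aggregate conformers and report tautomer stabilities for one molecule."""
    ensemble = MoleculeEnsemble.from_records(records, molecule_id, phase)
    result = molecule_gibbs_energy(ensemble, params, constants)
    rel = relative_tautomer_energies(result.G_per_tautomer)
    pops = tautomer_populations(result.G_per_tautomer, constants)
    ranking = stability_ranking(rel)
    return TautomerReport(
        molecule_id=ensemble.molecule_id,
        column=column or ensemble.phase.value,
        relative_energies=rel,
        populations=pops,
        dominant=ranking[0],
    )


@dataclass(frozen=True)
class RankShiftReport:
    """Cross-solvent concordance of tautomer stability orderings."""

    per_molecule: pd.DataFrame
    n_shifts: int

    @property
    def concordant(self) -> bool:
        return self.n_shifts == 0


def rank_shift_report(
    columns: Mapping[str, Mapping[str, Mapping[str, float]]],
    min_population: float = 1e-6,
    constants: ThermoConstants = STANDARD,
) -> RankShiftReport:
    """Detect tautomer stability-ranking changes across solvent/model columns.

    Parameters
    ----------
    columns : mapping
        ``{column_label: {molecule: {tautomer: G}}}``; energies may be
        absolute or relative (ranking is shift-invariant).  Every column
        must provide the same tautomer set for each molecule.
    min_population : float
        Concordance is assessed over the thermally resolvable microstates:
        those whose Boltzmann population reaches this threshold in at least
        one column.  The ordering of states with vanishing populations
        carries no physical content (and is below the resolution of the
        underlying energies), so it is excluded by default; pass 0 for a
        strict comparison of the full ordering.

    Returns
    -------
    RankShiftReport
        Per-molecule concordance flags and ranking strings, plus the total
        number of molecules whose resolvable ordering differs between any
        two columns.
    """
    if not columns:
        raise ValueError("need at least one column")
    labels = list(columns)
    molecules = set(columns[labels[0]])
    for label in labels[1:]:
        if set(columns[label]) != molecules:
            raise CoverageError(f"column {label!r} does not share the molecule set")
    rows = []
    n_shifts = 0
    for mol in sorted(molecules):
        tautsets = {label: set(columns[label][mol]) for label in labels}
        ref = tautsets[labels[0]]
        for label, ts in tautsets.items():
            if ts != ref:
                raise CoverageError(
                    f"tautomer sets of {mol} differ between columns "
                    f"{labels[0]!r} and {label!r}"
                )
        resolvable = set()
        for label in labels:
            pops = tautomer_populations(columns[label][mol], constants)
            resolvable |= {t for t, p in pops.items() if p >= min_population}
        if not resolvable:  # degenerate cutoff; keep the dominant states
            resolvable = {stability_ranking(columns[labels[0]][mol])[0]}
        rankings = {
            label: stability_ranking(
                {t: g for t, g in columns[label][mol].items() if t in resolvable}
            )
            for label in labels
        }
        concordant = len(set(rankings.values())) == 1
        if not concordant:
            n_shifts += 1
        rows.append(
            {
                "molecule_id": mol,
                "concordant": concordant,
                "n_resolvable": len(resolvable),
                **{
                    f"ranking_{label}": " < ".join(rankings[label])
                    for label in labels
                },
            }
        )
    return RankShiftReport(per_molecule=pd.DataFrame(rows), n_shifts=n_shifts)


def rank_shift_from_table(table: pd.DataFrame, **kwargs) -> RankShiftReport:
    """Adapter for wide relative-energy tables (microstate index x columns).

    The molecule identifier is taken as the microstate label up to the first
    underscore (e.g. ``SM02_micro003`` belongs to ``SM02``).  Keyword
    arguments are passed through to :func:`rank_shift_report`.
    """
    columns: Dict[str, Dict[str, Dict[str, float]]] = {
        str(col): {} for col in table.columns
    }
    for microstate, row in table.iterrows():
        mol = str(microstate).split("_", 1)[0]
        for col in table.columns:
            columns[str(col)].setdefault(mol, {})[str(microstate)] = float(row[col])
    return rank_shift_report(columns, **kwargs)
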