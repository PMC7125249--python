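"""Typed data model for per-state energy components and correction parameters.

The central object is the :class:`StateRecord`: one row of precomputed
EC-RISM/3D RISM energy components for a single (molecule, tautomer,
conformer, phase) combination.  Solution-phase rows carry the electronic
energy in solution ``E_sol``, the uncorrected excess chemical potential
``mu_ex`` and the partial molar volume ``V_m``; vacuum rows carry only the
gas-phase electronic energy ``E_vac``.  The net charge ``q`` is a molecular
property and must be identical across every state of a molecule.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ValidationError


class Phase(str, Enum):
    """Solvent environment of a state.

    ``octanol_dry`` is pure n-octanol; ``octanol_wet`` is water-saturated
    n-octanol (water mole fraction ~0.27).  ``vacuum`` marks gas-phase
    reference conformations.
    """

    water = "water"
    octanol_dry = "octanol_dry"
    octanol_wet = "octanol_wet"
    vacuum = "vacuum"


#: Phases that represent a condensed solvent environment.
SOLUTION_PHASES = frozenset({Phase.water, Phase.octanol_dry, Phase.octanol_wet})


class StateRecord(BaseModel):
    """Energy components of one (molecule, tautomer, conformer, phase) state.

    Energies are kcal/mol, ``V_m`` is in cubic angstrom and ``q`` in units of
    the elementary charge.  An absent field means the quantity is undefined
    for the phase, never that it is zero.
    """

    model_config = ConfigDict(frozen=True)

    molecule_id: str
    tautomer_id: str
    conformer_id: str
    phase: Phase
    E_sol: Optional[float] = None
    E_vac: Optional[float] = None
    mu_ex: Optional[float] = None
    V_m: Optional[float] = None
    q: int = 0

    @model_validator(mode="after")
    def _check_phase_fields(self) -> "StateRecord":
        if self.phase is Phase.vacuum:
            if self.E_vac is None:
                raise ValueError(
                    f"vacuum state {self.key()} must carry E_vac"
                )
            if self.mu_ex is not None or self.V_m is not None:
                raise ValueError(
                    f"vacuum state {self.key()} must not carry mu_ex or V_m"
                )
        else:
            missing = [
                name
                for name in ("E_sol", "mu_ex", "V_m")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(
                    f"solution state {self.key()} is missing {', '.join(missing)}"
                )
        return self

    def key(self) -> tuple[str, str, str, str]:
        """Unique identity of the state."""
        return (self.molecule_id, self.tautomer_id, self.conformer_id, self.phase.value)


class Observable(str, Enum):
    """Experimental observable type."""

    dGsolv = "dGsolv"
    logP = "logP"


class ExperimentRecord(BaseModel):
    """One experimental reference value.

    ``solvent`` is required for solvation Gibbs energies (kcal/mol) and
    ignored for partition coefficients (log units).
    """

    model_config = ConfigDict(frozen=True)

    molecule_id: str
    observable: Observable
    solvent: Optional[Phase] = None
    value: float

    @model_validator(mode="after")
    def _check_solvent(self) -> "ExperimentRecord":
        if self.observable is Observable.dGsolv:
            if self.solvent is None or self.solvent is Phase.vacuum:
                raise ValueError(
                    f"dGsolv record for {self.molecule_id} needs a solution-phase solvent"
                )
        return self


#: Names of the tunable coefficients of the correction model.
PARAM_NAMES = ("c_mu", "c_V", "c_q")


class CorrectionParams(BaseModel):
    """Coefficients of the corrected excess chemical potential.

    mu_corr = c_mu * mu_ex + c_V * V_m + c_q * q

    ``c_mu`` is dimensionless, ``c_V`` in kcal mol^-1 A^-3 and ``c_q`` in
    kcal mol^-1 e^-1.  ``free_mask`` records which coefficients were (or are
    to be) fitted; fixed coefficients keep their preset values through
    training.
    """

    model_config = ConfigDict(frozen=True)

    solvent_label: str = ""
    c_mu: float = 1.0
    c_V: float = 0.0
    c_q: float = 0.0
    free_mask: Mapping[str, bool] = {"c_mu": False, "c_V": False, "c_q": False}

    @model_validator(mode="after")
    def _check_mask(self) -> "CorrectionParams":
        extra = set(self.free_mask) - set(PARAM_NAMES)
        if extra:
            raise ValueError(f"unknown parameter names in free_mask: {sorted(extra)}")
        full = {name: bool(self.free_mask.get(name, False)) for name in PARAM_NAMES}
        object.__setattr__(self, "free_mask", full)
        return self

    def free_names(self) -> tuple[str, ...]:
        """Names of the coefficients marked as fitted."""
        return tuple(name for name in PARAM_NAMES if self.free_mask[name])

    def with_values(self, **values: float) -> "CorrectionParams":
        """Return a copy with some coefficients replaced."""
        return self.model_copy(update=values)


class ReassignmentMap(BaseModel):
    """Explicit conformer-to-tautomer reassignment.

    Maps (molecule_id, conformer_id, phase) to the corrected tautomer label
    for conformations whose protonation topology changed during upstream
    structure optimization.
    """

    model_config = ConfigDict(frozen=True)

    entries: Mapping[tuple[str, str, Phase], str] = {}

    def __len__(self) -> int:
        return len(self.entries)


def validate_states(records: Sequence[StateRecord]) -> Sequence[StateRecord]:
    """Enforce collection-level invariants on a state table.

    Raises
    ------
    ValidationError
        On a duplicate (molecule, tautomer, conformer, phase) key or a net
        charge that varies within a molecule.
    """
    seen: set[tuple[str, str, str, str]] = set()
    charge: dict[str, int] = {}
    for rec in records:
        key = rec.key()
        if key in seen:
            raise ValidationError(f"duplicate state key {key}")
        seen.add(key)
        prev = charge.setdefault(rec.molecule_id, rec.q)
        if prev != rec.q:
            raise ValidationError(
                f"net charge of {rec.molecule_id} is inconsistent: "
                f"{prev} vs {rec.q} (q must not vary across tautomers/conformers)"
            )
    return records


def molecule_ids(records: Iterable[StateRecord]) -> list[str]:
    """Sorted unique molecule identifiers in a state table."""
    return sorted({rec.molecule_id for rec in records})
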