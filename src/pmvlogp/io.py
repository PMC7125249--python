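"""Reading and writing of state tables, experiment tables and parameter files.

State and experiment tables are plain TSV/CSV with a header row; an empty
cell means "absent" (zero is a legal value and never means absent).  Model
parameters are stored as a small JSON object.  All text is UTF-8 with "."
as the decimal separator; scientific notation is accepted on read.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from pydantic import ValidationError as PydanticValidationError

from .datamodel import (
    CorrectionParams,
    ExperimentRecord,
    Observable,
    Phase,
    ReassignmentMap,
    StateRecord,
    validate_states,
)
from .errors import FormatError, ValidationError

PathLike = Union[str, Path]

STATE_COLUMNS = [
    "molecule_id",
    "tautomer_id",
    "conformer_id",
    "phase",
    "E_sol",
    "E_vac",
    "mu_ex",
    "V_m",
    "q",
]

EXPERIMENT_COLUMNS = ["molecule_id", "observable", "solvent", "value"]

REASSIGNMENT_COLUMNS = ["molecule_id", "conformer_id", "phase", "new_tautomer_id"]


def _sep(path: PathLike, dialect: Optional[str]) -> str:
    if dialect is None:
        dialect = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    return "\t" if dialect == "tsv" else ","


def _opt(value: object) -> Optional[float]:
    """Translate a pandas cell to float-or-absent."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_state_table(path: PathLike, dialect: Optional[str] = None) -> list[StateRecord]:
    """Read and validate a per-state energy-component table.

    Parameters
    ----------
    path : path
        TSV or CSV file with header
        ``molecule_id, tautomer_id, conformer_id, phase, E_sol, E_vac, mu_ex, V_m, q``.
    dialect : {"tsv", "csv"}, optional
        Field separator; inferred from the file suffix when omitted.

    Returns
    -------
    list of StateRecord
        Row order preserved; all record- and collection-level invariants
        enforced.
    """
    frame = pd.read_csv(
        path,
        sep=_sep(path, dialect),
        dtype={"molecule_id": str, "tautomer_id": str, "conformer_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in STATE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"state table {path} is missing column(s): {', '.join(missing)}"
        )
    records = []
    for row in frame.itertuples(index=False):
        q = _opt(row.q)
        try:
            records.append(
                StateRecord(
                    molecule_id=row.molecule_id,
                    tautomer_id=row.tautomer_id,
                    conformer_id=row.conformer_id,
                    phase=Phase(row.phase),
                    E_sol=_opt(row.E_sol),
                    E_vac=_opt(row.E_vac),
                    mu_ex=_opt(row.mu_ex),
                    V_m=_opt(row.V_m),
                    q=0 if q is None else int(q),
                )
            )
        except (PydanticValidationError, ValueError) as exc:
            raise ValidationError(f"invalid state row in {path}: {exc}") from exc
    validate_states(records)
    return records


def write_state_table(
    records: Sequence[StateRecord], path: PathLike, dialect: Optional[str] = None
) -> None:
    """Write a state table; inverse of :func:`read_state_table`.

    Numeric fields are written with ``repr`` precision so that a read/write
    round trip is lossless.
    """
    frame = pd.DataFrame(
        [
            {
                "molecule_id": r.molecule_id,
                "tautomer_id": r.tautomer_id,
                "conformer_id": r.conformer_id,
                "phase": r.phase.value,
                "E_sol": r.E_sol,
                "E_vac": r.E_vac,
                "mu_ex": r.mu_ex,
                "V_m": r.V_m,
                "q": r.q,
            }
            for r in records
        ],
        columns=STATE_COLUMNS,
    )
    frame.to_csv(path, sep=_sep(path, dialect), index=False, float_format="%.17g")


def read_experiment_table(
    path: PathLike, dialect: Optional[str] = None
) -> list[ExperimentRecord]:
    """Read an experimental reference table.

    Header: ``molecule_id, observable, solvent, value``; ``observable`` is
    ``dGsolv`` (kcal/mol, requires a solvent) or ``logP`` (log units,
    solvent cell empty).
    """
    frame = pd.read_csv(
        path,
        sep=_sep(path, dialect),
        dtype={"molecule_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in EXPERIMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"experiment table {path} is missing column(s): {', '.join(missing)}"
        )
    records = []
    seen = set()
    for row in frame.itertuples(index=False):
        solvent = row.solvent
        if isinstance(solvent, float) and math.isnan(solvent):
            solvent = None
        try:
            rec = ExperimentRecord(
                molecule_id=row.molecule_id,
                observable=Observable(row.observable),
                solvent=None if solvent is None else Phase(solvent),
                value=float(row.value),
            )
        except (PydanticValidationError, ValueError) as exc:
            raise ValidationError(f"invalid experiment row in {path}: {exc}") from exc
        key = (rec.molecule_id, rec.observable, rec.solvent)
        if key in seen:
            raise ValidationError(f"duplicate experiment record {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_experiment_table(
    records: Sequence[ExperimentRecord], path: PathLike, dialect: Optional[str] = None
) -> None:
    """Write an experiment table; inverse of :func:`read_experiment_table`."""
    frame = pd.DataFrame(
        [
            {
                "molecule_id": r.molecule_id,
                "observable": r.observable.value,
                "solvent": None if r.solvent is None else r.solvent.value,
                "value": r.value,
            }
            for r in records
        ],
        columns=EXPERIMENT_COLUMNS,
    )
    frame.to_csv(path, sep=_sep(path, dialect), index=False, float_format="%.17g")


def write_params(params: CorrectionParams, path: PathLike, T: Optional[float] = None) -> None:
    """Serialize correction parameters to JSON.

    The optional temperature is stored alongside so a parameter file fully
    specifies the model it was trained for.
    """
    payload = {
        "solvent_label": params.solvent_label,
        "c_mu": params.c_mu,
        "c_V": params.c_V,
        "c_q": params.c_q,
        "free_mask": dict(params.free_mask),
    }
    if T is not None:
        payload["T"] = T
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_params(path: PathLike) -> CorrectionParams:
    """Read a JSON parameter file written by :func:`write_params`."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed parameter file {path}: {exc}") from exc
    missing = [k for k in ("solvent_label", "c_mu", "c_V", "c_q") if k not in payload]
    if missing:
        raise FormatError(
            f"parameter file {path} is missing field(s): {', '.join(missing)}"
        )
    return CorrectionParams(
        solvent_label=payload["solvent_label"],
        c_mu=float(payload["c_mu"]),
        c_V=float(payload["c_V"]),
        c_q=float(payload["c_q"]),
        free_mask=payload.get("free_mask", {}),
    )


def read_reassignment_map(path: PathLike, dialect: Optional[str] = None) -> ReassignmentMap:
    """Read a conformer-to-tautomer reassignment table.

    Header: ``molecule_id, conformer_id, phase, new_tautomer_id``.
    """
    frame = pd.read_csv(path, sep=_sep(path, dialect), dtype=str)
    missing = [c for c in REASSIGNMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"reassignment table {path} is missing column(s): {', '.join(missing)}"
        )
    entries = {}
    for row in frame.itertuples(index=False):
        entries[(row.molecule_id, row.conformer_id, Phase(row.phase))] = (
            row.new_tautomer_id
        )
    return ReassignmentMap(entries=entries)


def states_to_frame(records: Sequence[StateRecord]) -> pd.DataFrame:
    """State records as a pandas DataFrame (one row per state)."""
    return pd.DataFrame(
        [
            {
                "molecule_id": r.molecule_id,
                "tautomer_id": r.tautomer_id,
                "conformer_id": r.conformer_id,
                "phase": r.phase.value,
                "E_sol": r.E_sol,
                "E_vac": r.E_vac,
                "mu_ex": r.mu_ex,
                "V_m": r.V_m,
                "q": r.q,
            }
            for r in records
        ],
        columns=STATE_COLUMNS,
    )
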