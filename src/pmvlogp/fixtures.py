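"""Built-in reference datasets and correction-parameter presets.

Three small tables from the SAMPL6 log P study ship with the package:

``table1_params``
    Trained correction coefficients and training-set statistics of the
    solvation Gibbs energy models (water; dry/wet n-octanol, 1-/2-parameter).
``table2_logp``
    Experimental and predicted log P of the 11 SAMPL6 challenge compounds
    for all four octanol models.
``table4_relative_energies``
    Gibbs energies of the neutral microstates relative to the most stable
    tautomer of each compound, per solvent/model column (kcal/mol).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datamodel import CorrectionParams

FIXTURE_NAMES = ("table1_params", "table2_logp", "table4_relative_energies")


def _read(name: str) -> pd.DataFrame:
    with resources.files("pmvlogp.data").joinpath(f"{name}.csv").open("r") as handle:
        return pd.read_csv(handle)


def load_builtin_fixture(name: str) -> pd.DataFrame:
    """Load one of the shipped reference tables.

    Parameters
    ----------
    name : {"table1_params", "table2_logp", "table4_relative_energies"}

    Returns
    -------
    pandas.DataFrame
        ``table1_params`` indexed by (solvent, model); ``table2_logp``
        indexed by molecule_id with the experimental column ``logP_exp`` and
        four model columns; ``table4_relative_energies`` indexed by
        microstate with one column per solvent/model.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    frame = _read(name)
    if name == "table1_params":
        return frame.set_index(["solvent", "model"])
    if name == "table2_logp":
        return frame.set_index("molecule_id")
    return frame.set_index("microstate")


#: Fixture column label per (solvent, model) of the log P table.
LOGP_MODEL_COLUMNS = {
    ("octanol_dry", "1-par"): "dry_1par",
    ("octanol_wet", "1-par"): "wet_1par",
    ("octanol_dry", "2-par"): "dry_2par",
    ("octanol_wet", "2-par"): "wet_2par",
}


def correction_preset(solvent: str, model: str = "2-par") -> CorrectionParams:
    """Trained correction parameters for a solvent model.

    Parameters
    ----------
    solvent : {"water", "octanol_dry", "octanol_wet"}
        Water uses the fixed three-term model (c_mu = 1, fitted c_V and c_q);
        the octanol presets come in a PMV-only ("1-par") and a scaled
        ("2-par") variant.
    model : {"1-par", "2-par"}
        Ignored for water.

    Returns
    -------
    CorrectionParams
        Coefficients exactly as trained, with ``free_mask`` marking which
        were fitted.
    """
    table = load_builtin_fixture("table1_params")
    if solvent == "water":
        row = table.loc[("water", "all")]
        return CorrectionParams(
            solvent_label="water",
            c_mu=1.0,
            c_V=float(row["c_V"]),
            c_q=float(row["c_q"]),
            free_mask={"c_mu": False, "c_V": True, "c_q": True},
        )
    try:
        row = table.loc[(solvent, model)]
    except KeyError as exc:
        raise KeyError(f"no preset for solvent={solvent!r}, model={model!r}") from exc
    c_mu = row["c_mu"]
    fit_mu = model == "2-par"
    return CorrectionParams(
        solvent_label=f"{solvent}_{model}",
        c_mu=1.0 if pd.isna(c_mu) else float(c_mu),
        c_V=float(row["c_V"]),
        c_q=0.0,
        free_mask={"c_mu": fit_mu, "c_V": True, "c_q": False},
    )
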