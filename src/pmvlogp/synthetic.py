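"""Synthetic component datasets with known ground-truth correction parameters.

The generator emulates the *shape* of EC-RISM/3D RISM component tables —
large negative absolute electronic energies, excess chemical potentials
roughly linear in the partial molar volume, a handful of tautomers with
low-energy conformer spreads — without any attempt to be physically
faithful to real quantum-chemical or integral-equation output.  Noiseless
experimental observables are computed from the generator's own true
correction parameters through the package's forward model, then perturbed
with additive Gaussian noise, so that training, prediction and the error
analyses are fully testable with a known answer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .constants import STANDARD, ThermoConstants
from .datamodel import (
    CorrectionParams,
    ExperimentRecord,
    Observable,
    Phase,
    StateRecord,
    validate_states,
)
from .io import write_experiment_table, write_state_table
from .thermo import (
    MoleculeEnsemble,
    log_partition_coefficient,
    molecule_gibbs_energy,
    vacuum_gibbs_energy,
)


def _default_true_params() -> Dict[str, CorrectionParams]:
    return {
        Phase.water.value: CorrectionParams(
            solvent_label="water",
            c_mu=1.0,
            c_V=-0.10251,
            c_q=-15.728,
            free_mask={"c_mu": False, "c_V": True, "c_q": True},
        ),
        Phase.octanol_wet.value: CorrectionParams(
            solvent_label="octanol_wet",
            c_mu=1.3,
            c_V=-0.01,
            c_q=0.0,
            free_mask={"c_mu": True, "c_V": True, "c_q": False},
        ),
    }


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation conditions for one synthetic dataset.

    Defaults: 200 neutral molecules with 1-3 tautomers of 1-5 conformers
    each, partial molar volumes uniform on [50, 400] A^3, excess chemical
    potentials linear in V_m with negative slope plus molecule-level noise
    (covering roughly [-40, 5] kcal/mol), conformer energy spreads
    exponential with mean 1 kcal/mol, and 0.3 kcal/mol of additive Gaussian
    noise on the experimental solvation Gibbs energies.
    """

    n_molecules: int = 200
    tautomer_range: Tuple[int, int] = (1, 3)
    conformer_range: Tuple[int, int] = (1, 5)
    true_params: Mapping[str, CorrectionParams] = field(
        default_factory=_default_true_params
    )
    vm_range: Tuple[float, float] = (50.0, 400.0)
    mu_slope: float = -0.11
    mu_intercept: float = 5.5
    mu_molecule_sd: float = 2.0
    mu_state_sd: float = 0.5
    conformer_spread_mean: float = 1.0
    tautomer_gap_range: Tuple[float, float] = (2.0, 12.0)
    sigma: float = 0.3
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        for name in ("tautomer_range", "conformer_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi, got {(lo, hi)}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.true_params:
            raise ValueError("need at least one solvent in true_params")

    def to_json(self) -> str:
        payload = asdict(self)
        payload["true_params"] = {
            k: p.model_dump() for k, p in self.true_params.items()
        }
        return json.dumps(payload, indent=2)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated state/experiment tables plus the generating ground truth."""

    spec: SyntheticSpec
    states: Mapping[str, Sequence[StateRecord]]  # solvent phases + "vacuum"
    experiments: Sequence[ExperimentRecord]
    true_params: Mapping[str, CorrectionParams]
    noiseless_dgsolv: Mapping[str, Mapping[str, float]]  # solvent -> molecule -> value
    noiseless_logp: Mapping[str, float]
    class_labels: Optional[Mapping[str, str]] = None

    def all_states(self) -> list[StateRecord]:
        """Solution and vacuum states as one flat validated table."""
        flat = [r for recs in self.states.values() for r in recs]
        validate_states(flat)
        return flat

    def write(self, directory: Union[str, Path]) -> None:
        """Write the standard TSV tables plus ground_truth.json."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_state_table(self.all_states(), directory / "states.tsv")
        write_experiment_table(self.experiments, directory / "experiments.tsv")
        truth = {
            "spec": json.loads(self.spec.to_json()),
            "true_params": {k: p.model_dump() for k, p in self.true_params.items()},
            "noiseless_dgsolv": {
                k: dict(v) for k, v in self.noiseless_dgsolv.items()
            },
            "noiseless_logp": dict(self.noiseless_logp),
        }
        if self.class_labels is not None:
            truth["class_labels"] = dict(self.class_labels)
        (directory / "ground_truth.json").write_text(
            json.dumps(truth, indent=2) + "\n", encoding="utf-8"
        )


def _molecule_states(
    rng: np.random.Generator, spec: SyntheticSpec, mol: str
) -> tuple[Dict[str, list[StateRecord]], list[StateRecord]]:
    """Generate solution states per solvent plus vacuum states for one molecule."""
    solvents = list(spec.true_params)
    n_taut = int(rng.integers(spec.tautomer_range[0], spec.tautomer_range[1] + 1))
    # Gas-phase-like tautomer offsets; solvent-specific modulation below.
    taut_offsets = np.concatenate(
        ([0.0], np.sort(rng.uniform(*spec.tautomer_gap_range, size=n_taut - 1)))
    )
    E0 = rng.uniform(-1e5, -1e4)
    V0 = rng.uniform(*spec.vm_range)
    mu0 = spec.mu_slope * V0 + spec.mu_intercept + rng.normal(0.0, spec.mu_molecule_sd)
    solvation_shift = {s: rng.normal(0.0, 2.0) for s in solvents}
    solution: Dict[str, list[StateRecord]] = {s: [] for s in solvents}
    vacuum: list[StateRecord] = []
    for t in range(n_taut):
        taut = f"{mol}_micro{t + 1:03d}"
        for solvent in solvents:
            n_conf = int(
                rng.integers(spec.conformer_range[0], spec.conformer_range[1] + 1)
            )
            spread = np.concatenate(
                (
                    [0.0],
                    rng.exponential(spec.conformer_spread_mean, size=n_conf - 1),
                )
            )
            for c, dE in enumerate(spread):
                V = max(10.0, V0 + rng.normal(0.0, 2.0))
                mu = mu0 + rng.normal(0.0, spec.mu_state_sd)
                solution[solvent].append(
                    StateRecord(
                        molecule_id=mol,
                        tautomer_id=taut,
                        conformer_id=f"c{c}",
                        phase=Phase(solvent),
                        E_sol=E0
                        + taut_offsets[t]
                        + solvation_shift[solvent]
                        + rng.normal(0.0, 0.5)
                        + dE,
                        mu_ex=mu,
                        V_m=V,
                        q=0,
                    )
                )
        n_vac = int(rng.integers(spec.conformer_range[0], spec.conformer_range[1] + 1))
        vac_spread = np.concatenate(
            ([0.0], rng.exponential(spec.conformer_spread_mean, size=n_vac - 1))
        )
        for c, dE in enumerate(vac_spread):
            vacuum.append(
                StateRecord(
                    molecule_id=mol,
                    tautomer_id=taut,
                    conformer_id=f"v{c}",
                    phase=Phase.vacuum,
                    E_vac=E0 + taut_offsets[t] + rng.normal(0.0, 0.5) + dE,
                    q=0,
                )
            )
    return solution, vacuum


def _observables(
    states: Mapping[str, Sequence[StateRecord]],
    true_params: Mapping[str, CorrectionParams],
    constants: ThermoConstants,
) -> tuple[Dict[str, Dict[str, float]], Dict[str, float]]:
    """Noiseless dGsolv per solvent and log P from the forward model."""
    solvents = [s for s in states if s != Phase.vacuum.value]
    molecules = sorted({r.molecule_id for r in states[solvents[0]]})
    vac_by_mol: Dict[str, list[StateRecord]] = {}
    for r in states[Phase.vacuum.value]:
        vac_by_mol.setdefault(r.molecule_id, []).append(r)
    dgsolv: Dict[str, Dict[str, float]] = {s: {} for s in solvents}
    g_abs: Dict[str, Dict[str, float]] = {s: {} for s in solvents}
    for solvent in solvents:
        for mol in molecules:
            ens = MoleculeEnsemble.from_records(states[solvent], molecule_id=mol)
            g = molecule_gibbs_energy(ens, true_params[solvent], constants).G_total
            g_abs[solvent][mol] = g
            dgsolv[solvent][mol] = g - vacuum_gibbs_energy(vac_by_mol[mol], constants)
    logp: Dict[str, float] = {}
    if Phase.water.value in g_abs and len(solvents) >= 2:
        octanol = next(
            (s for s in solvents if s.startswith("octanol")), None
        )
        if octanol is not None:
            for mol in molecules:
                logp[mol] = log_partition_coefficient(
                    g_abs[Phase.water.value][mol], g_abs[octanol][mol], constants
                )
    return dgsolv, logp


def generate_dataset(
    spec: SyntheticSpec, constants: ThermoConstants = STANDARD
) -> SyntheticDataset:
    """Generate a reproducible synthetic dataset.

    All randomness flows from ``spec.seed`` through a single generator, so
    identical specs produce bit-identical datasets.  The noiseless ground
    truth observables satisfy the package's thermodynamic relations exactly
    under ``spec.true_params``.
    """
    rng = np.random.default_rng(spec.seed)
    solvents = list(spec.true_params)
    states: Dict[str, list[StateRecord]] = {s: [] for s in solvents}
    states[Phase.vacuum.value] = []
    width = max(4, len(str(spec.n_molecules)))
    for i in range(spec.n_molecules):
        mol = f"MOL{i + 1:0{width}d}"
        solution, vacuum = _molecule_states(rng, spec, mol)
        for s in solvents:
            states[s].extend(solution[s])
        states[Phase.vacuum.value].extend(vacuum)
    dgsolv, logp = _observables(states, spec.true_params, constants)
    experiments: list[ExperimentRecord] = []
    noisy_dg: Dict[str, Dict[str, float]] = {}
    for solvent in solvents:
        noisy_dg[solvent] = {}
        for mol, value in dgsolv[solvent].items():
            noisy = value + rng.normal(0.0, spec.sigma)
            noisy_dg[solvent][mol] = noisy
            experiments.append(
                ExperimentRecord(
                    molecule_id=mol,
                    observable=Observable.dGsolv,
                    solvent=Phase(solvent),
                    value=noisy,
                )
            )
    if logp:
        octanol = next(s for s in solvents if s.startswith("octanol"))
        for mol in sorted(logp):
            # Experimental log P consistent with the noisy per-phase dGsolv.
            value = (
                noisy_dg[Phase.water.value][mol] - noisy_dg[octanol][mol]
            ) / constants.RT_ln10
            experiments.append(
                ExperimentRecord(
                    molecule_id=mol, observable=Observable.logP, value=value
                )
            )
    return SyntheticDataset(
        spec=spec,
        states={k: tuple(v) for k, v in states.items()},
        experiments=tuple(experiments),
        true_params=dict(spec.true_params),
        noiseless_dgsolv=dgsolv,
        noiseless_logp=logp,
    )


def generate_outlier_scenario(
    spec: SyntheticSpec,
    outlier_offset: Union[float, Mapping[str, float]],
    n_outliers: Optional[int] = None,
    outlier_label: str = "alcohol",
    base_label: str = "other",
    constants: ThermoConstants = STANDARD,
) -> SyntheticDataset:
    """Dataset with a class-wise systematic water-vs-octanol error offset.

    A labeled subset of molecules has its experimental water dGsolv shifted
    so that predictions made with the true parameters show a constant
    signed error of ``offset`` (kcal/mol) in water, zero in octanol, and
    hence ``offset / (RT ln 10)`` in log P — mirroring a compound class
    whose aqueous solvation is systematically mispredicted.

    Parameters
    ----------
    outlier_offset : float or mapping
        A single offset applied to ``n_outliers`` molecules (labelled
        ``outlier_label``; everyone else ``base_label`` with zero offset),
        or ``{class_label: offset}`` distributing all molecules round-robin
        across the given classes.
    """
    if isinstance(outlier_offset, Mapping):
        offsets = dict(outlier_offset)
        if not offsets:
            raise ValueError("offset mapping must not be empty")
    else:
        if n_outliers is None:
            n_outliers = max(1, spec.n_molecules // 5)
        if n_outliers < 1 or n_outliers > spec.n_molecules:
            raise ValueError(
                f"n_outliers must be in [1, {spec.n_molecules}], got {n_outliers}"
            )
        offsets = None
    base = generate_dataset(spec, constants)
    molecules = sorted(base.noiseless_dgsolv[next(iter(base.noiseless_dgsolv))])
    rng = np.random.default_rng(spec.seed + 1)
    labels: Dict[str, str] = {}
    offset_by_mol: Dict[str, float] = {}
    if offsets is None:
        chosen = set(
            rng.choice(molecules, size=n_outliers, replace=False).tolist()
        )
        for mol in molecules:
            if mol in chosen:
                labels[mol] = outlier_label
                offset_by_mol[mol] = float(outlier_offset)
            else:
                labels[mol] = base_label
                offset_by_mol[mol] = 0.0
    else:
        class_names = list(offsets)
        for i, mol in enumerate(molecules):
            cls = class_names[i % len(class_names)]
            labels[mol] = cls
            offset_by_mol[mol] = float(offsets[cls])
    experiments = []
    for rec in base.experiments:
        shift = offset_by_mol[rec.molecule_id]
        if shift == 0.0:
            experiments.append(rec)
        elif rec.observable is Observable.dGsolv and rec.solvent is Phase.water:
            # prediction - experiment = +shift in water
            experiments.append(rec.model_copy(update={"value": rec.value - shift}))
        elif rec.observable is Observable.logP:
            experiments.append(
                rec.model_copy(
                    update={"value": rec.value - shift / constants.RT_ln10}
                )
            )
        else:
            experiments.append(rec)
    return SyntheticDataset(
        spec=spec,
        states=base.states,
        experiments=tuple(experiments),
        true_params=base.true_params,
        noiseless_dgsolv=base.noiseless_dgsolv,
        noiseless_logp=base.noiseless_logp,
        class_labels=labels,
    )
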