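"""Nonlinear regression of the correction coefficients.

The correction coefficients (c_mu, c_V, and optionally c_q) are trained by
minimizing the squared deviation of partition-function solvation Gibbs
energies from experimental values,

    L = sum_molecules ( -RT ln sum_tc exp[-(E_sol + c_mu*mu_ex + c_V*V_m
            + c_q*q)/RT]  +  RT ln sum_tc' exp[-E_vac/RT]
            - dGsolv_exp )^2

where the second sum runs over the pooled gas-phase conformers.  Because
the free coefficients appear inside the exponents, the problem is genuinely
nonlinear whenever a molecule has more than one state; with one state per
molecule it reduces to ordinary least squares.

The reference octanol models in :mod:`pmvlogp.fixtures` were trained this
way on the Minnesota Solvation Database (224 molecules with experimental
n-octanol solvation Gibbs energies).  That database and the accompanying
component-energy tables are external data: users who have them can re-fit
via :func:`fit_correction_params` as an optional validation; the package
itself ships only the resulting presets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .constants import STANDARD, ThermoConstants
from .datamodel import (
    SOLUTION_PHASES,
    CorrectionParams,
    ExperimentRecord,
    Observable,
    Phase,
    StateRecord,
)
from .errors import CoverageError, DegenerateDataError

logger = logging.getLogger(__name__)

#: Multi-start grid for the simplex optimizer.
START_GRID = {
    "c_mu": (0.5, 1.0, 1.5),
    "c_V": (0.0, -0.01, -0.1),
    "c_q": (0.0, -15.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which correction coefficients are fitted.

    ``n_params=1`` fixes c_mu at 1 and fits only the PMV coefficient c_V;
    ``n_params=2`` fits c_mu and c_V.  ``fit_cq`` additionally frees the
    charge coefficient and is only meaningful for datasets containing
    charged species.
    """

    n_params: int = 2
    fit_cq: bool = False
    fixed_values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_params not in (1, 2):
            raise ValueError("n_params must be 1 or 2")

    def free_names(self) -> Tuple[str, ...]:
        names = ["c_V"] if self.n_params == 1 else ["c_mu", "c_V"]
        if self.fit_cq:
            names.append("c_q")
        return tuple(names)

    def base_params(self, solvent_label: str = "") -> CorrectionParams:
        values = {"c_mu": 1.0, "c_V": 0.0, "c_q": 0.0}
        values.update(self.fixed_values)
        free = self.free_names()
        return CorrectionParams(
            solvent_label=solvent_label,
            free_mask={name: name in free for name in values},
            **values,
        )


@dataclass(frozen=True)
class OptimizerSettings:
    """Simplex convergence tolerances and evaluation budget."""

    fatol: float = 1e-10
    xatol: float = 1e-8
    maxiter: int = 4000


class TrainingDataset:
    """Per-molecule component arrays paired with experimental dGsolv values.

    Built from a state table (solution states of one solvent plus vacuum
    states) and an experiment table.  Solution and vacuum states are stored
    as contiguous segments so the loss can be evaluated with vectorized
    segment log-sum-exp operations.
    """

    def __init__(
        self,
        states: Sequence[StateRecord],
        experiments: Sequence[ExperimentRecord],
        solvent: Phase,
        strict: bool = True,
    ) -> None:
        if solvent not in SOLUTION_PHASES:
            raise ValueError(f"solvent must be a solution phase, got {solvent}")
        self.solvent = solvent
        exp_map = {
            r.molecule_id: r.value
            for r in experiments
            if r.observable is Observable.dGsolv and r.solvent == solvent
        }
        sol: Dict[str, list[StateRecord]] = {}
        vac: Dict[str, list[StateRecord]] = {}
        for r in states:
            if r.phase == solvent:
                sol.setdefault(r.molecule_id, []).append(r)
            elif r.phase is Phase.vacuum:
                vac.setdefault(r.molecule_id, []).append(r)
        molecules = sorted(sol)
        missing_vac = [m for m in molecules if m not in vac]
        if missing_vac:
            raise CoverageError(
                "molecule(s) without vacuum states: " + ", ".join(missing_vac)
            )
        missing_exp = [m for m in molecules if m not in exp_map]
        if missing_exp:
            if strict:
                raise CoverageError(
                    f"molecule(s) without experimental dGsolv in {solvent.value}: "
                    + ", ".join(missing_exp)
                )
            logger.warning(
                "excluding %d molecule(s) without experimental dGsolv", len(missing_exp)
            )
            molecules = [m for m in molecules if m in exp_map]
        if not molecules:
            raise CoverageError("no trainable molecules in dataset")
        self.molecule_ids: list[str] = molecules

        def _segments(groups, fields):
            arrays = {f: [] for f in fields}
            counts = []
            for m in molecules:
                rows = groups[m]
                counts.append(len(rows))
                for f in fields:
                    arrays[f].extend(getattr(r, f) for r in rows)
            counts = np.asarray(counts, dtype=int)
            starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
            return {f: np.asarray(v, dtype=float) for f, v in arrays.items()}, starts, counts

        sol_arrays, self._sol_starts, self._sol_counts = _segments(
            sol, ("E_sol", "mu_ex", "V_m", "q")
        )
        self._E_sol = sol_arrays["E_sol"]
        self._mu = sol_arrays["mu_ex"]
        self._V = sol_arrays["V_m"]
        self._q = sol_arrays["q"]
        vac_arrays, self._vac_starts, self._vac_counts = _segments(vac, ("E_vac",))
        self._E_vac = vac_arrays["E_vac"]
        self.y_exp = np.asarray([exp_map[m] for m in molecules], dtype=float)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    def _segment_free_energy(self, g: np.ndarray, starts, counts, rt: float) -> np.ndarray:
        shift = np.minimum.reduceat(g, starts)
        z = np.add.reduceat(np.exp(-(g - np.repeat(shift, counts)) / rt), starts)
        return shift - rt * np.log(z)

    def vacuum_energies(self, constants: ThermoConstants) -> np.ndarray:
        """Pooled gas-phase free energy per molecule (parameter-independent)."""
        return self._segment_free_energy(
            self._E_vac, self._vac_starts, self._vac_counts, constants.RT
        )

    def model_dgsolv(
        self, params: CorrectionParams, constants: ThermoConstants
    ) -> np.ndarray:
        """Per-molecule solvation Gibbs energy under the given coefficients."""
        g = (
            self._E_sol
            + params.c_mu * self._mu
            + params.c_V * self._V
            + params.c_q * self._q
        )
        g_sol = self._segment_free_energy(g, self._sol_starts, self._sol_counts, constants.RT)
        return g_sol - self.vacuum_energies(constants)

    def column(self, name: str) -> np.ndarray:
        """Data column controlled by a coefficient (for degeneracy checks)."""
        return {"c_mu": self._mu, "c_V": self._V, "c_q": self._q}[name]

    def subset(self, indices: Sequence[int]) -> "TrainingDataset":
        """Molecule-level resample (with possible repetition) for bootstrap."""
        new = object.__new__(TrainingDataset)
        new.solvent = self.solvent
        new.molecule_ids = [self.molecule_ids[i] for i in indices]
        parts_sol = [
            (
                self._E_sol[s : s + c],
                self._mu[s : s + c],
                self._V[s : s + c],
                self._q[s : s + c],
            )
            for s, c in (
                (self._sol_starts[i], self._sol_counts[i]) for i in indices
            )
        ]
        new._E_sol = np.concatenate([p[0] for p in parts_sol])
        new._mu = np.concatenate([p[1] for p in parts_sol])
        new._V = np.concatenate([p[2] for p in parts_sol])
        new._q = np.concatenate([p[3] for p in parts_sol])
        new._sol_counts = np.asarray([self._sol_counts[i] for i in indices], dtype=int)
        new._sol_starts = np.concatenate(([0], np.cumsum(new._sol_counts)[:-1]))
        new._E_vac = np.concatenate(
            [
                self._E_vac[self._vac_starts[i] : self._vac_starts[i] + self._vac_counts[i]]
                for i in indices
            ]
        )
        new._vac_counts = np.asarray([self._vac_counts[i] for i in indices], dtype=int)
        new._vac_starts = np.concatenate(([0], np.cumsum(new._vac_counts)[:-1]))
        new.y_exp = self.y_exp[list(indices)]
        return new


@dataclass(frozen=True)
class FitResult:
    """Outcome of a correction-parameter fit."""

    params: CorrectionParams
    loss_value: float
    n_molecules: int
    converged: bool
    n_evaluations: int
    per_molecule_residuals: Mapping[str, float]


def training_loss(
    params: CorrectionParams,
    dataset: TrainingDataset,
    constants: ThermoConstants = STANDARD,
) -> float:
    """Sum of squared dGsolv residuals (kcal^2 mol^-2) at given coefficients."""
    residuals = dataset.model_dgsolv(params, constants) - dataset.y_exp
    return float(residuals @ residuals)


def _check_degeneracy(dataset: TrainingDataset, free_names: Sequence[str]) -> None:
    for name in free_names:
        if np.allclose(dataset.column(name), 0.0):
            raise DegenerateDataError(
                f"loss is independent of {name}: its data column is identically zero"
            )


def fit_correction_params(
    dataset: TrainingDataset,
    spec: ModelSpec,
    settings: Optional[OptimizerSettings] = None,
    constants: ThermoConstants = STANDARD,
    solvent_label: str = "",
    starts: Optional[Sequence[Sequence[float]]] = None,
) -> FitResult:
    """Fit the free correction coefficients by least squares.

    Runs a derivative-free Nelder-Mead simplex from every point of a small
    multi-start grid and keeps the best local minimum; deterministic for
    fixed settings.

    Raises
    ------
    DegenerateDataError
        When a free coefficient multiplies a data column that is identically
        zero, which would make the loss flat along that coordinate.
    CoverageError
        Propagated from dataset construction when molecules lack vacuum
        states or experimental values.
    """
    settings = settings or OptimizerSettings()
    free = spec.free_names()
    if dataset.n_molecules < len(free):
        raise CoverageError(
            f"need at least {len(free)} molecules to fit {len(free)} parameters"
        )
    _check_degeneracy(dataset, free)
    base = spec.base_params(solvent_label or dataset.solvent.value)

    def loss_vec(x: np.ndarray) -> float:
        return training_loss(
            base.with_values(**dict(zip(free, x))), dataset, constants
        )

    if starts is None:
        grids = [START_GRID[name] for name in free]
        starts = np.array(np.meshgrid(*grids)).reshape(len(free), -1).T
    best = None
    n_eval = 0
    for x0 in starts:
        res = minimize(
            loss_vec,
            np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            options={
                "fatol": settings.fatol,
                "xatol": settings.xatol,
                "maxiter": settings.maxiter,
            },
        )
        n_eval += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    fitted = base.with_values(**dict(zip(free, (float(v) for v in best.x))))
    residuals = dataset.model_dgsolv(fitted, constants) - dataset.y_exp
    return FitResult(
        params=fitted,
        loss_value=float(residuals @ residuals),
        n_molecules=dataset.n_molecules,
        converged=bool(best.success),
        n_evaluations=n_eval,
        per_molecule_residuals=dict(zip(dataset.molecule_ids, residuals.tolist())),
    )


def bootstrap_parameter_uncertainty(
    dataset: TrainingDataset,
    spec: ModelSpec,
    n_resamples: int = 200,
    seed: int = 0,
    constants: ThermoConstants = STANDARD,
    level: float = 0.95,
) -> Dict[str, Tuple[float, float]]:
    """Molecule-level bootstrap percentile intervals for the free coefficients.

    Each resample draws molecules with replacement and re-fits, warm-started
    at the full-data estimate.  Reproducible for a fixed seed.  At least 100
    resamples are recommended for stable interval endpoints.

    Returns
    -------
    dict
        ``{coefficient: (lower, upper)}`` percentile bounds at ``level``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    free = spec.free_names()
    full = fit_correction_params(dataset, spec, constants=constants)
    x_full = [getattr(full.params, name) for name in free]
    rng = np.random.default_rng(seed)
    samples: list[list[float]] = []
    n = dataset.n_molecules
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        if len({dataset.molecule_ids[i] for i in idx}) < len(free):
            logger.warning("skipping degenerate bootstrap resample")
            continue
        sub = dataset.subset(list(idx))
        try:
            fit = fit_correction_params(
                sub, spec, constants=constants, starts=[x_full]
            )
        except DegenerateDataError:
            logger.warning("skipping degenerate bootstrap resample")
            continue
        samples.append([getattr(fit.params, name) for name in free])
    if not samples:
        raise DegenerateDataError("all bootstrap resamples were degenerate")
    arr = np.asarray(samples)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(arr, alpha, axis=0)
    hi = np.quantile(arr, 1.0 - alpha, axis=0)
    return {name: (float(l), float(h)) for name, l, h in zip(free, lo, hi)}
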