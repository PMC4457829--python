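"""Mass-conserving first-order reaction network and its propagation.

The network has eight protein species: CO-bound r and t, ligand in the
primary docking site (r and t), ligand in the secondary docking site (r and
t), and unliganded r and t with the ligand in solvent.  CO is in
pseudo-first-order excess, so its solution concentration enters only through
the bimolecular entry fluxes ``kin_x * [CO]`` and the dynamics are linear.

Populations are dimensionless fractions of total protein; they are
non-negative and sum to one along every trajectory.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .exceptions import (
    DegenerateEquilibriumError,
    IntegrationError,
    InvalidParameterError,
)
from .rates import ExperimentConditions, RateConstants

#: Species names, in state-vector order.
SPECIES = (
    "R_CO", "T_CO",
    "R_dock1", "T_dock1",
    "R_dock2", "T_dock2",
    "R_free", "T_free",
)
R_CO, T_CO, R_DOCK1, T_DOCK1, R_DOCK2, T_DOCK2, R_FREE, T_FREE = range(8)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class StateVector:
    """Populations of the eight species, as fractions of total protein."""

    populations: np.ndarray

    def __post_init__(self):
        pops = np.asarray(self.populations, dtype=float)
        if pops.shape != (len(SPECIES),):
            raise InvalidParameterError(
                f"state vector must have shape ({len(SPECIES)},), got {pops.shape}"
            )
        if not np.all(np.isfinite(pops)):
            raise InvalidParameterError("state vector contains non-finite populations")
        if np.any(pops < -_SUM_TOL):
            raise InvalidParameterError(f"negative population: {pops.min()}")
        if abs(pops.sum() - 1.0) > _SUM_TOL:
            raise InvalidParameterError(f"populations sum to {pops.sum()}, expected 1")
        object.__setattr__(self, "populations", np.clip(pops, 0.0, None))

    def __getitem__(self, species: str | int) -> float:
        if isinstance(species, str):
            species = SPECIES.index(species)
        return float(self.populations[species])

    def as_dict(self) -> dict[str, float]:
        return {name: float(p) for name, p in zip(SPECIES, self.populations)}

    @property
    def bound_fraction(self) -> float:
        return float(self.populations[R_CO] + self.populations[T_CO])


@dataclass
class KineticTrace:
    """A time grid with a normalized kinetic observable.

    ``signal`` is the unliganded fraction N(t) for photolysis traces or the
    bound fraction for dissociation traces.  When produced by a simulation,
    the full species time courses are attached as an ``(8, n)`` array.
    """

    times: np.ndarray
    signal: np.ndarray
    noise_sigma: float | None = None
    species: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.signal.shape:
            raise InvalidParameterError("times and signal must be 1-D arrays of equal length")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if self.signal.size and (self.signal.min() < -0.05 or self.signal.max() > 1.05):
            raise InvalidParameterError(
                "signal outside the [-0.05, 1.05] tolerance band: "
                f"range [{self.signal.min()}, {self.signal.max()}]"
            )

    def __len__(self) -> int:
        return self.times.size

    def species_course(self, name: str) -> np.ndarray:
        if self.species is None:
            raise InvalidParameterError("this trace carries no species time courses")
        return self.species[SPECIES.index(name)]


def log_times(t_min: float = 1e-8, t_max: float = 1.0, per_decade: int = 200) -> np.ndarray:
    """Logarithmically spaced time grid, ``per_decade`` points per decade."""
    if not 0 < t_min < t_max:
        raise InvalidParameterError("need 0 < t_min < t_max")
    n = int(round(np.log10(t_max / t_min) * per_decade)) + 1
    return np.logspace(np.log10(t_min), np.log10(t_max), n)


def build_rate_matrix(
    rates: RateConstants,
    co_molar: float,
    scavenger_mode: bool = False,
) -> np.ndarray:
    """First-order generator matrix A such that dy/dt = A @ y.

    Columns index the source species and sum to zero (mass conservation by
    construction); off-diagonal entries are the non-negative rate constants,
    with the solvent-entry fluxes ``kin_x * co_molar`` (zeroed in scavenger
    mode).
    """
    if not np.isfinite(co_molar) or co_molar < 0:
        raise InvalidParameterError(f"co_molar must be >= 0, got {co_molar!r}")
    r = rates
    a = np.zeros((8, 8))

    def add(src: int, dst: int, rate: float) -> None:
        a[dst, src] += rate
        a[src, src] -= rate

    add(R_CO, T_CO, r.k1)
    add(T_CO, R_CO, r.k_1)
    add(R_DOCK1, T_DOCK1, r.k2)
    add(T_DOCK1, R_DOCK1, r.k_2)
    add(R_FREE, T_FREE, r.k3)
    add(T_FREE, R_FREE, r.k_3)
    add(R_DOCK1, R_DOCK2, r.kc)
    add(R_DOCK2, R_DOCK1, r.k_c)
    add(T_DOCK1, T_DOCK2, r.kd2)
    add(T_DOCK2, T_DOCK1, r.k_d2)
    add(R_DOCK1, R_CO, r.kg_r)
    add(R_CO, R_DOCK1, r.kdiss_r)
    add(T_DOCK1, T_CO, r.kg_t)
    add(T_CO, T_DOCK1, r.kdiss_t)
    add(R_DOCK1, R_FREE, r.kout)
    add(T_DOCK1, T_FREE, r.kout)
    if not scavenger_mode:
        add(R_FREE, R_DOCK1, r.kin_r * co_molar)
        add(T_FREE, T_DOCK1, r.kin_t * co_molar)
    return a


def bound_equilibrium_state(rates: RateConstants) -> StateVector:
    """Fully CO-bound pre-flash (or pre-mix) state, with the bound population
    split between the r and t conformers as 1 : (k1/k_1)."""
    if rates.k1 > 0 and rates.k_1 == 0:
        raise DegenerateEquilibriumError(
            "k1 > 0 with k_1 = 0: the bound-state equilibrium is undefined"
        )
    k1_ratio = rates.k1 / rates.k_1 if rates.k1 > 0 else 0.0
    pops = np.zeros(8)
    pops[R_CO] = 1.0 / (1.0 + k1_ratio)
    pops[T_CO] = k1_ratio / (1.0 + k1_ratio)
    return StateVector(pops)


def photolysis_initial_state(
    rates: RateConstants, conditions: ExperimentConditions
) -> StateVector:
    """State immediately after the laser flash.

    A fraction ``photolysis_yield`` of each bound conformer is promoted to its
    primary docking site; the remainder stays bound.  Secondary sites and the
    solvent start empty.
    """
    eq = bound_equilibrium_state(rates).populations
    y = conditions.photolysis_yield
    pops = np.zeros(8)
    pops[R_CO] = eq[R_CO] * (1.0 - y)
    pops[T_CO] = eq[T_CO] * (1.0 - y)
    pops[R_DOCK1] = eq[R_CO] * y
    pops[T_DOCK1] = eq[T_CO] * y
    return StateVector(pops)


def propagate(
    matrix: np.ndarray,
    y0: np.ndarray,
    times: np.ndarray,
    method: str = "stiff",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> np.ndarray:
    """Propagate dy/dt = A y from t = 0 to each requested time.

    ``method='stiff'`` integrates with the implicit BDF solver; ``'eig'``
    evaluates the exact solution through the eigendecomposition of A (the
    system is linear and time-invariant), falling back to stepwise matrix
    exponentials if the eigenbasis is ill-conditioned.  The returned
    populations are projected back onto the conservation manifold
    (sum = 1) to remove residual solver drift.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] < 0 or not np.all(np.diff(times) > 0):
        raise InvalidParameterError("times must be strictly increasing and start at >= 0")
    if method == "stiff":
        sol = solve_ivp(
            lambda t, y: matrix @ y,
            (0.0, times[-1]),
            y0,
            method="BDF",
            t_eval=times,
            jac=lambda t, y: matrix,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            t_fail = float(sol.t[-1]) if sol.t.size else 0.0
            raise IntegrationError(f"stiff integration failed at t = {t_fail}: {sol.message}", t_fail)
        out = sol.y
    elif method == "eig":
        out = _propagate_eig(matrix, y0, times)
    else:
        raise InvalidParameterError(f"unknown propagation method {method!r}")
    return _project_conserved(out, float(np.sum(y0)))


def _propagate_eig(matrix: np.ndarray, y0: np.ndarray, times: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(matrix)
    cond = np.linalg.cond(v)
    if not np.isfinite(cond) or cond > 1e10:
        # Defective or near-defective generator: step with matrix exponentials.
        out = np.empty((y0.size, times.size))
        y = np.asarray(y0, dtype=float)
        t_prev = 0.0
        for i, t in enumerate(times):
            y = expm(matrix * (t - t_prev)) @ y
            t_prev = t
            out[:, i] = y
        return out
    c = np.linalg.solve(v, y0.astype(complex))
    # A generator matrix has eigenvalues with non-positive real part; clamp
    # tiny positive numerical noise so the exponentials cannot overflow.
    expo = np.outer(np.minimum(w.real, 0.0), times) + 1j * np.outer(w.imag, times)
    out = (v @ (c[:, None] * np.exp(expo))).real
    if not np.all(np.isfinite(out)):
        raise IntegrationError("eigendecomposition propagation produced non-finite values")
    return out


def _project_conserved(y: np.ndarray, total: float) -> np.ndarray:
    y = np.clip(y, 0.0, None)
    sums = y.sum(axis=0)
    if total > 0 and (np.any(sums <= 0) or np.max(np.abs(sums - total)) > 1e-6):
        raise IntegrationError(
            f"mass-conservation drift too large: max |sum - {total}| = "
            f"{np.max(np.abs(sums - total))}"
        )
    if total > 0:
        y = y * (total / sums)
    return y


def simulate_trace(
    rates: RateConstants,
    conditions: ExperimentConditions,
    times: np.ndarray,
    method: str = "stiff",
    initial_state: StateVector | None = None,
) -> KineticTrace:
    """Simulate the flash-photolysis rebinding observable N(t).

    N(t) = 1 - (bound r + bound t) is the unliganded fraction; by
    construction N(0) equals the photolysis yield.  The full species time
    courses (the reaction intermediates) are attached to the returned trace.
    """
    if initial_state is None:
        initial_state = photolysis_initial_state(rates, conditions)
    a = build_rate_matrix(rates, conditions.co_molar, conditions.scavenger_mode)
    y = propagate(a, initial_state.populations, times, method=method)
    signal = 1.0 - (y[R_CO] + y[T_CO])
    return KineticTrace(times=times, signal=signal, species=y)


def simulate_no_displacement(
    rates: RateConstants,
    conditions: ExperimentConditions,
    times: np.ndarray,
    freeze_interconversion: bool = False,
    method: str = "stiff",
) -> KineticTrace:
    """Simulate the stopped-flow NO-displacement dissociation experiment.

    Starts from the pre-mix bound equilibrium and propagates with solvent
    rebinding disabled (the scavenger consumes free sites); the observable is
    the remaining bound fraction.  With ``freeze_interconversion`` the
    r <-> t exchange of the bound and primary-docked states is switched off,
    so the two dissociation pathways stay independent and the decay is
    biexponential with apparent rates ``kdiss_x * kout / (kout + kg_x)`` in
    the separated-timescale regime.
    """
    if not conditions.scavenger_mode:
        raise InvalidParameterError(
            "simulate_no_displacement requires conditions.scavenger_mode=True"
        )
    y0 = bound_equilibrium_state(rates)
    run_rates = rates
    if freeze_interconversion:
        run_rates = rates.replace(k1=0.0, k_1=0.0, k2=0.0, k_2=0.0)
    a = build_rate_matrix(run_rates, conditions.co_molar, scavenger_mode=True)
    y = propagate(a, y0.populations, times, method=method)
    return KineticTrace(times=times, signal=y[R_CO] + y[T_CO], species=y)
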