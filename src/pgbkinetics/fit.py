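"""Global fitting of rebinding traces and derived kinetic constants.

The rebinding model is fitted simultaneously to traces recorded at several
CO pressures; all rate constants are shared between traces.  Parameters can
be fixed, tied to other parameters (k2 := k3, k_2 := k_3), or derived from
measured stopped-flow off-rates through the dissociation branching relation.
Optimization runs in log10 parameter space (rates are positive and span many
orders of magnitude) with a robust local least-squares minimizer started from
several jittered initializations.

Per-parameter errors follow the fitness-scan convention: each free parameter
is scanned around the optimum with the others held fixed, and the half-width
of the scan curve at a 10% increase of the fitness function is reported,
cross-checked against the error-matrix (Gauss-Newton covariance) estimate.
"""
from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares, nnls

from .exceptions import (
    DegenerateEquilibriumError,
    IntegrationError,
    InvalidParameterError,
)
from .kinetics import KineticTrace, R_DOCK1, T_DOCK1, StateVector, log_times, simulate_trace
from .rates import RATE_FIELDS, ExperimentConditions, RateConstants, kdiss_from_koff

logger = logging.getLogger(__name__)

#: Parameters whose fitted value is ignored because it is derived from a
#: measured off-rate: derived map pathway -> target field.
_DERIVED_TARGETS = {"r": "kdiss_r", "t": "kdiss_t"}

#: Relative Jacobian column norm below which a parameter is reported as
#: having negligible sensitivity.
_SENSITIVITY_FLOOR = 1e-3


@dataclass
class FitSpec:
    """Specification of a global fit.

    Parameters
    ----------
    initial:
        Starting rate constants.
    data:
        List of ``(trace, conditions)`` pairs sharing all rate parameters.
    fixed:
        Parameter names held at their initial value.
    ties:
        ``target := source`` map enforced exactly during the fit
        (e.g. ``{"k2": "k3", "k_2": "k_3"}``).
    derived_koff:
        Measured off-rates keyed by pathway (``"r"``/``"t"``); the
        corresponding ``kdiss_r``/``kdiss_t`` are held to
        ``koff * (kout + kg) / kout`` at the current kout/kg.
    """

    initial: RateConstants
    data: list[tuple[KineticTrace, ExperimentConditions]] = field(default_factory=list)
    fixed: frozenset = frozenset()
    ties: dict = field(default_factory=dict)
    derived_koff: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fixed = frozenset(self.fixed)
        unknown = (self.fixed | set(self.ties) | set(self.ties.values())) - set(RATE_FIELDS)
        if unknown:
            raise InvalidParameterError(f"unknown parameter names: {sorted(unknown)}")
        for pathway in self.derived_koff:
            if pathway not in _DERIVED_TARGETS:
                raise InvalidParameterError(f"derived_koff pathway must be 'r' or 't', got {pathway!r}")
        # A parameter must be controlled exactly once.
        controlled = list(self.fixed) + list(self.ties) + [
            _DERIVED_TARGETS[p] for p in self.derived_koff
        ]
        dupes = {n for n in controlled if controlled.count(n) > 1}
        if dupes:
            raise InvalidParameterError(f"parameters controlled more than once: {sorted(dupes)}")
        self._check_ties_acyclic()

    def _check_ties_acyclic(self):
        for start in self.ties:
            seen, node = {start}, self.ties[start]
            while node in self.ties:
                if node in seen:
                    raise InvalidParameterError(f"tie map contains a cycle through {node!r}")
                seen.add(node)
                node = self.ties[node]

    @property
    def free_names(self) -> tuple:
        controlled = set(self.fixed) | set(self.ties) | {
            _DERIVED_TARGETS[p] for p in self.derived_koff
        }
        return tuple(n for n in RATE_FIELDS if n not in controlled)

    def realize(self, x_log: np.ndarray) -> RateConstants:
        """Rate constants implied by a log10 free-parameter vector."""
        values = self.initial.as_dict()
        for name, xv in zip(self.free_names, x_log):
            values[name] = 10.0 ** float(xv)
        # Ties may chain; the map is acyclic so |ties| passes suffice.
        for _ in range(max(1, len(self.ties))):
            for target, source in self.ties.items():
                values[target] = values[source]
        for pathway, koff in self.derived_koff.items():
            kg = values[f"kg_{pathway}"]
            values[_DERIVED_TARGETS[pathway]] = kdiss_from_koff(koff, values["kout"], kg)
        return RateConstants(**values)

    def initial_x(self) -> np.ndarray:
        x = []
        for name in self.free_names:
            v = getattr(self.initial, name)
            if v <= 0:
                raise InvalidParameterError(
                    f"free parameter {name} must have a positive initial value to be "
                    "fitted in log space; fix it instead"
                )
            x.append(np.log10(v))
        return np.asarray(x)


@dataclass
class ScanError:
    """Fitness-scan error of one parameter: half-widths of the scan curve at
    a ``threshold`` x minimum fitness, on each side of the optimum."""

    p_opt: float
    lower: float
    upper: float
    unbounded_lower: bool = False
    unbounded_upper: bool = False

    @property
    def halfwidth(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def relative(self) -> float:
        return self.halfwidth / self.p_opt if self.p_opt else np.inf

    @property
    def unbounded(self) -> bool:
        return self.unbounded_lower or self.unbounded_upper

    @property
    def weak(self) -> bool:
        """Weakly identified: the fitness stays flat to the edge of the scan
        range on some side, or the half-width exceeds half the value itself."""
        return self.unbounded or self.relative > 0.5


@dataclass
class FitResult:
    """Outcome of :func:`global_fit`."""

    rates: RateConstants
    rss: float
    free_names: tuple
    x_log: np.ndarray
    cov_log: np.ndarray | None
    param_sigma: dict
    diagnostics: dict
    warnings: list
    converged: bool
    scan: dict | None = None


def _residual_builder(spec: FitSpec, method: str):
    n_total = sum(len(trace) for trace, _ in spec.data)

    def residuals(x_log: np.ndarray) -> np.ndarray:
        try:
            rates = spec.realize(x_log)
            parts = []
            for trace, cond in spec.data:
                model = simulate_trace(rates, cond, trace.times, method=method)
                parts.append(model.signal - trace.signal)
            return np.concatenate(parts)
        except (IntegrationError, InvalidParameterError, np.linalg.LinAlgError) as exc:
            logger.debug("residual evaluation failed (%s); returning penalty", exc)
            return np.full(n_total, 1e3)

    return residuals


def global_fit(
    spec: FitSpec,
    method: str = "eig",
    n_starts: int = 3,
    jitter: float = 0.15,
    seed: int = 1234,
    max_nfev: int | None = None,
) -> FitResult:
    """Globally fit the kinetic scheme to all traces in ``spec``.

    Parameters are optimized in log10 space with ``scipy.optimize.least_squares``
    from ``n_starts`` initializations (the nominal one plus log-normal jitter of
    ``jitter`` decades, seeded).  Tied, derived and fixed parameters are honored
    exactly.  ``method`` selects the trace propagator ('eig' is the exact
    linear-system solution and is much faster inside the fit loop; 'stiff' is
    the BDF integrator).
    """
    if not spec.data:
        raise InvalidParameterError("FitSpec contains no traces")
    if not spec.free_names:
        raise InvalidParameterError("FitSpec leaves no free parameters")
    residuals = _residual_builder(spec, method)
    x0 = spec.initial_x()
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(0.0, jitter, x0.size) for _ in range(n_starts - 1)]

    best = None
    start_costs = []
    for x_start in starts:
        sol = least_squares(
            residuals,
            x_start,
            bounds=(x0 - 6.0, x0 + 6.0),
            method="trf",
            x_scale="jac",
            max_nfev=max_nfev,
        )
        start_costs.append(float(sol.cost))
        if best is None or sol.cost < best.cost:
            best = sol

    rss = float(2.0 * best.cost)
    jac = best.jac
    m, n = jac.shape
    colnorms = np.linalg.norm(jac, axis=0)
    warn_list = []
    scale = colnorms.max() if colnorms.size else 0.0
    for name, cn in zip(spec.free_names, colnorms):
        if scale == 0 or cn / scale < _SENSITIVITY_FLOOR:
            warn_list.append(f"parameter {name} has negligible sensitivity in this fit")

    cov_log = None
    param_sigma = {}
    if m > n:
        s2 = rss / (m - n)
        try:
            cov_log = s2 * np.linalg.pinv(jac.T @ jac)
            for i, name in enumerate(spec.free_names):
                p = 10.0 ** best.x[i]
                param_sigma[name] = p * np.log(10.0) * float(np.sqrt(max(cov_log[i, i], 0.0)))
        except np.linalg.LinAlgError:
            warn_list.append("error-matrix estimate is singular")

    converged = bool(best.status > 0)
    if not converged:
        warn_list.append(f"fit did not converge: {best.message}; best-so-far parameters returned")
    return FitResult(
        rates=spec.realize(best.x),
        rss=rss,
        free_names=spec.free_names,
        x_log=best.x.copy(),
        cov_log=cov_log,
        param_sigma=param_sigma,
        diagnostics={
            "status": int(best.status),
            "message": str(best.message),
            "nfev": int(best.nfev),
            "n_starts": len(starts),
            "start_costs": start_costs,
            "method": method,
        },
        warnings=warn_list,
        converged=converged,
    )


def scan_halfwidth(
    fitness,
    p_opt: float,
    n_points: int = 81,
    decades: float = 1.0,
    threshold: float = 1.1,
) -> ScanError:
    """Half-widths of a 1-D fitness curve at ``threshold`` x its value at
    ``p_opt``, scanned over ``p_opt`` x 10^[-decades, +decades].

    The scan grid brackets the crossing and a scalar root-finder refines it on
    the actual fitness function, so the result is accurate well below the grid
    resolution.
    """
    if p_opt <= 0:
        raise InvalidParameterError("scan requires a positive parameter value")
    if n_points < 5 or n_points % 2 == 0:
        raise InvalidParameterError("n_points must be odd and >= 5")
    f0 = float(fitness(p_opt))
    target = threshold * f0
    half = n_points // 2
    result = {}
    for side, sign in (("upper", 1.0), ("lower", -1.0)):
        grid = p_opt * 10.0 ** (sign * decades * np.arange(1, half + 1) / half)
        width = None
        prev_p = p_opt
        for p in grid:
            f = float(fitness(p))
            if f >= target:
                if f0 == 0:
                    width = abs(prev_p - p_opt)
                else:
                    lo, hi = (prev_p, p) if prev_p < p else (p, prev_p)
                    root = brentq(lambda q: fitness(q) - target, lo, hi, xtol=1e-12 * p_opt)
                    width = abs(root - p_opt)
                break
            prev_p = p
        if width is None:
            result[side] = (abs(grid[-1] - p_opt), True)
        else:
            result[side] = (width, False)
    return ScanError(
        p_opt=p_opt,
        lower=result["lower"][0],
        upper=result["upper"][0],
        unbounded_lower=result["lower"][1],
        unbounded_upper=result["upper"][1],
    )


def scan_errors(
    result: FitResult,
    spec: FitSpec,
    n_points: int = 81,
    decades: float = 1.0,
    threshold: float = 1.1,
    method: str | None = None,
) -> dict:
    """Fitness-scan errors for every free parameter of a converged fit.

    Each free parameter is scanned with the others fixed at the optimum; the
    half-width where the summed squared residual reaches ``threshold`` times
    its minimum is the reported error.  Parameters whose fitness stays flat
    across the scan range are flagged unbounded (weakly identified).  Results
    are also attached to ``result.scan``.
    """
    method = method or result.diagnostics.get("method", "eig")
    residuals = _residual_builder(spec, method)
    x_opt = result.x_log
    out = {}
    for i, name in enumerate(result.free_names):
        def fitness(p, _i=i):
            x = x_opt.copy()
            x[_i] = np.log10(p)
            r = residuals(x)
            return float(r @ r)

        out[name] = scan_halfwidth(
            fitness, 10.0 ** x_opt[i], n_points=n_points, decades=decades, threshold=threshold
        )
    result.scan = out
    return out


@dataclass
class MultiExpFit:
    """Sum-of-exponentials description of a decay: lifetimes sorted ascending,
    amplitudes normalized to fractions summing to one."""

    lifetimes: np.ndarray
    amplitudes: np.ndarray
    residual: float
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.lifetimes = np.asarray(self.lifetimes, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.lifetimes <= 0):
            raise InvalidParameterError("lifetimes must be positive")
        total = self.amplitudes.sum()
        if total > 0:
            self.amplitudes = self.amplitudes / total


def _multiexp_design(t: np.ndarray, taus: np.ndarray) -> np.ndarray:
    expo = -t[:, None] / taus[None, :]
    return np.exp(np.clip(expo, -700.0, 0.0))


def fit_multiexponential(
    trace: KineticTrace,
    n: int,
    n_starts: int = 4,
    seed: int = 0,
) -> MultiExpFit:
    """Least-squares fit of ``sum_i a_i exp(-t / tau_i)`` to a trace.

    Lifetimes are optimized in log10 space by variable projection (amplitudes
    solved by non-negative least squares at every step), from several
    seeded initializations spread over the time range.  Amplitudes are
    returned as fractions; nearly degenerate lifetimes (ratio < 1.5) trigger
    an ill-conditioning warning.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    t, s = trace.times, trace.signal
    if t.size < 3 * n:
        raise InvalidParameterError(f"need at least {3 * n} points to fit {n} exponentials")

    def residuals(theta):
        taus = 10.0 ** theta
        design = _multiexp_design(t, taus)
        amps, _ = nnls(design, s)
        return design @ amps - s

    lo, hi = np.log10(t[0] if t[0] > 0 else t[1]), np.log10(t[-1])
    theta0 = lo + (hi - lo) * (np.arange(1, n + 1) / (n + 1.0))
    rng = np.random.default_rng(seed)
    starts = [theta0] + [theta0 + rng.normal(0.0, 0.3, n) for _ in range(n_starts - 1)]

    best = None
    for theta_start in starts:
        sol = least_squares(residuals, theta_start, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol

    taus = 10.0 ** best.x
    design = _multiexp_design(t, taus)
    amps, _ = nnls(design, s)
    order = np.argsort(taus)
    taus, amps = taus[order], amps[order]
    warn_list = []
    if n > 1 and np.any(taus[1:] / taus[:-1] < 1.5):
        warn_list.append("adjacent lifetimes within a factor 1.5: fit is ill-conditioned")
        _warnings.warn(warn_list[-1], RuntimeWarning, stacklevel=2)
    rss = float(2.0 * best.cost)
    return MultiExpFit(lifetimes=taus, amplitudes=amps, residual=rss, warnings=warn_list)


@dataclass(frozen=True)
class DerivedConstants:
    """Equilibrium and second-order constants implied by a rate set.

    ``kon_*_branching`` is the closed-form estimate ``kin * kg / (kg + kout)``;
    ``kon_*_numeric`` is measured from simulated traces as the slope of the
    apparent bimolecular rate versus [CO].  Both are reported because they are
    independent consistency checks on the microscopic constants.
    """

    K1: float
    K3: float
    kdiss_r: float
    kdiss_t: float
    kon_r_branching: float
    kon_t_branching: float
    kon_r_numeric: float | None = None
    kon_t_numeric: float | None = None


def _numeric_kon(rates: RateConstants, pathway: str, co_pair, method: str) -> float:
    """Apparent second-order rebinding constant of one pathway, measured as the
    slope of the fitted bimolecular rate versus [CO] on simulated traces."""
    kin = getattr(rates, f"kin_{pathway}")
    kg = getattr(rates, f"kg_{pathway}")
    kon_est = kin * kg / (kg + rates.kout) if (kg + rates.kout) > 0 else 0.0
    if kin == 0 or kon_est <= 0:
        return float("nan")
    # Isolate the pathway: no conformational exchange, all ligand starts in
    # this conformer's primary docking site.
    iso = rates.replace(k1=0.0, k_1=0.0, k2=0.0, k_2=0.0, k3=0.0, k_3=0.0,
                        kdiss_r=0.0, kdiss_t=0.0)
    y0 = np.zeros(8)
    y0[R_DOCK1 if pathway == "r" else T_DOCK1] = 1.0
    state = StateVector(y0)
    lams = []
    for c in co_pair:
        lam_est = kon_est * c
        t_lo = 50.0 / (kg + rates.kout)
        t_hi = 5.0 / lam_est
        if t_lo >= t_hi:
            return float("nan")
        times = log_times(t_lo, t_hi, per_decade=40)
        cond = ExperimentConditions(co_pressure=c, co_solubility=1.0)
        trace = simulate_trace(iso, cond, times, method=method, initial_state=state)
        sub = KineticTrace(times=trace.times, signal=trace.signal)
        lam = 1.0 / fit_multiexponential(sub, 1).lifetimes[0]
        lams.append(lam)
    return float((lams[1] - lams[0]) / (co_pair[1] - co_pair[0]))


def derive_constants(
    rates: RateConstants,
    measured_koff_fast: float | None = None,
    measured_koff_slow: float | None = None,
    slow_pathway: str = "r",
    numeric: bool = True,
    co_molar_pair: tuple = (1e-4, 2e-4),
    method: str = "eig",
) -> DerivedConstants:
    """Equilibrium constants K1 and K3, thermal dissociation rates, and
    second-order CO binding constants implied by a set of microscopic rates.

    When measured off-rates are supplied, ``kdiss_r``/``kdiss_t`` are derived
    by inverting the branching relation (``kdiss = koff (kout + kg) / kout``);
    the slower phase is assigned to the ``slow_pathway`` conformer (r by
    default: the liganded equilibrium favors r, whose dissociation is slow).
    """
    if rates.k1 > 0 and rates.k_1 == 0:
        raise DegenerateEquilibriumError("K1 undefined: k1 > 0 with k_1 = 0")
    if rates.k3 > 0 and rates.k_3 == 0:
        raise DegenerateEquilibriumError("K3 undefined: k3 > 0 with k_3 = 0")
    if rates.k_1 == 0 or rates.k_3 == 0:
        raise DegenerateEquilibriumError("K1/K3 undefined: zero backward rate")
    if slow_pathway not in ("r", "t"):
        raise InvalidParameterError("slow_pathway must be 'r' or 't'")

    kdiss = {"r": rates.kdiss_r, "t": rates.kdiss_t}
    fast_pathway = "t" if slow_pathway == "r" else "r"
    if measured_koff_slow is not None:
        kg = getattr(rates, f"kg_{slow_pathway}")
        kdiss[slow_pathway] = kdiss_from_koff(measured_koff_slow, rates.kout, kg)
    if measured_koff_fast is not None:
        kg = getattr(rates, f"kg_{fast_pathway}")
        kdiss[fast_pathway] = kdiss_from_koff(measured_koff_fast, rates.kout, kg)

    def branching(pathway):
        kin = getattr(rates, f"kin_{pathway}")
        kg = getattr(rates, f"kg_{pathway}")
        return kin * kg / (kg + rates.kout) if (kg + rates.kout) > 0 else 0.0

    kon_r_num = kon_t_num = None
    if numeric:
        kon_r_num = _numeric_kon(rates, "r", co_molar_pair, method)
        kon_t_num = _numeric_kon(rates, "t", co_molar_pair, method)
    return DerivedConstants(
        K1=rates.k1 / rates.k_1,
        K3=rates.k3 / rates.k_3,
        kdiss_r=kdiss["r"],
        kdiss_t=kdiss["t"],
        kon_r_branching=branching("r"),
        kon_t_branching=branching("t"),
        kon_r_numeric=kon_r_num,
        kon_t_numeric=kon_t_num,
    )
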