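"""Microscopic rate constants and experimental conditions.

The kinetic scheme couples two tertiary conformations of the protein — a
"more reactive" r state (fast CO association, slow dissociation) and a "less
reactive" t state — each with a bound state, a primary and a secondary ligand
docking site, and an unliganded state exchanging ligand with the solvent.
Direction convention: ``k1``, ``k2``, ``k3`` are r -> t; the underscored
partners are t -> r.  This makes the liganded equilibrium ``K1 = k1/k_1``
favor r (K1 < 1) and the unliganded equilibrium ``K3 = k3/k_3`` favor t
(K3 > 1), as observed for MaPgb*.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .exceptions import InvalidParameterError

#: Field names of :class:`RateConstants`, in canonical order.
RATE_FIELDS = (
    "k1", "k_1", "k2", "k_2", "k3", "k_3",
    "kc", "k_c", "kd2", "k_d2",
    "kg_r", "kg_t", "kdiss_r", "kdiss_t",
    "kin_r", "kin_t", "kout",
)

#: Fields carrying second-order (M^-1 s^-1) units; all others are s^-1.
SECOND_ORDER_FIELDS = frozenset({"kin_r", "kin_t"})


@dataclass(frozen=True)
class RateConstants:
    """All microscopic rate constants of the reaction network.

    Attributes
    ----------
    k1, k_1:
        Interconversion of the CO-bound conformers, r.CO <-> t.CO (s^-1).
    k2, k_2:
        Interconversion of the primary-docking-site states,
        (r:CO)1 <-> (t:CO)1 (s^-1).  Usually tied to ``k3``/``k_3`` in fits.
    k3, k_3:
        Interconversion of the unliganded conformers, r <-> t (s^-1).
    kc, k_c:
        r-state migration between primary and secondary docking site (s^-1).
    kd2, k_d2:
        t-state migration between primary and secondary docking site (s^-1).
    kg_r, kg_t:
        Geminate Fe-CO bond re-formation from the primary docking site (s^-1).
    kdiss_r, kdiss_t:
        Thermal Fe-CO bond dissociation into the primary docking site (s^-1).
    kin_r, kin_t:
        Bimolecular ligand entry from the solvent (M^-1 s^-1).
    kout:
        Ligand escape from the primary docking site to the solvent (s^-1);
        a single value shared by both conformations.
    """

    k1: float = 0.0
    k_1: float = 0.0
    k2: float = 0.0
    k_2: float = 0.0
    k3: float = 0.0
    k_3: float = 0.0
    kc: float = 0.0
    k_c: float = 0.0
    kd2: float = 0.0
    k_d2: float = 0.0
    kg_r: float = 0.0
    kg_t: float = 0.0
    kdiss_r: float = 0.0
    kdiss_t: float = 0.0
    kin_r: float = 0.0
    kin_t: float = 0.0
    kout: float = 0.0

    def __post_init__(self):
        for name in RATE_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise InvalidParameterError(f"rate {name} must be a number, got {value!r}")
            if not math.isfinite(value) or value < 0:
                raise InvalidParameterError(
                    f"rate {name} must be finite and >= 0, got {value!r}"
                )
            object.__setattr__(self, name, float(value))

    def replace(self, **changes: float) -> "RateConstants":
        """Return a copy with the given fields changed."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATE_FIELDS}


@dataclass(frozen=True)
class ExperimentConditions:
    """Conditions of a photolysis or ligand-displacement experiment.

    Parameters
    ----------
    co_pressure:
        Equilibration CO pressure in atm.
    temperature:
        Temperature in degrees Celsius (informational; the scheme is
        single-temperature).
    co_solubility:
        Dissolved CO per atm of CO pressure, in M/atm.  Default 1.0 mM/atm
        near 20 C.
    photolysis_yield:
        Fraction of the bound population photodissociated by the laser flash,
        in [0, 1].
    scavenger_mode:
        When set, ligand re-entry from the solvent is disabled, modelling the
        stopped-flow NO-displacement experiment in which free sites are
        scavenged.
    """

    co_pressure: float = 1.0
    temperature: float = 20.0
    co_solubility: float = 1.0e-3
    photolysis_yield: float = 1.0
    scavenger_mode: bool = False

    def __post_init__(self):
        if not math.isfinite(self.co_pressure) or self.co_pressure < 0:
            raise InvalidParameterError(f"co_pressure must be >= 0, got {self.co_pressure!r}")
        if not math.isfinite(self.co_solubility) or self.co_solubility < 0:
            raise InvalidParameterError(f"co_solubility must be >= 0, got {self.co_solubility!r}")
        if not 0.0 <= self.photolysis_yield <= 1.0:
            raise InvalidParameterError(
                f"photolysis_yield must be in [0, 1], got {self.photolysis_yield!r}"
            )

    @property
    def co_molar(self) -> float:
        """Dissolved CO concentration in M."""
        return self.co_pressure * self.co_solubility

    def replace(self, **changes) -> "ExperimentConditions":
        return dataclasses.replace(self, **changes)


def apparent_off_rate(kdiss: float, kout: float, kg: float) -> float:
    """Apparent CO dissociation rate of one pathway under scavenging.

    In the separated-timescale regime (thermal bond breaking much slower than
    the internal docking-site kinetics) a ligand released into the primary
    docking site either rebinds (kg) or escapes (kout), so the measurable
    off-rate is ``kdiss * kout / (kout + kg)``.
    """
    if kout + kg <= 0:
        raise InvalidParameterError("kout + kg must be positive")
    return kdiss * kout / (kout + kg)


def kdiss_from_koff(koff: float, kout: float, kg: float) -> float:
    """Invert :func:`apparent_off_rate`: thermal bond-breaking rate implied by
    a measured off-rate ``koff``."""
    if kout <= 0:
        raise InvalidParameterError("kout must be positive to invert the branching relation")
    return koff * (kout + kg) / kout


@dataclass(frozen=True)
class VariantData:
    """Rate-constant set for one protein variant plus its measured stopped-flow
    CO dissociation phases (off-rates in s^-1, amplitudes as fractions)."""

    rates: RateConstants
    koff_slow: float
    koff_fast: float | None
    amp_slow: float
    amp_fast: float


def _variant(koff_slow, koff_fast, amp_slow, amp_fast, *, slow_pathway="r", **rates):
    """Build a VariantData, tying k2/k_2 to k3/k_3 and deriving kdiss_r/kdiss_t
    from the measured off-rates through the branching relation."""
    rates.setdefault("k2", rates["k3"])
    rates.setdefault("k_2", rates["k_3"])
    kout, kg_r, kg_t = rates["kout"], rates["kg_r"], rates["kg_t"]
    koff_r = koff_slow if slow_pathway == "r" else koff_fast
    koff_t = koff_fast if slow_pathway == "r" else koff_slow
    if koff_t is None:  # monophasic dissociation: one off-rate for both pathways
        koff_t = koff_r
    rc = RateConstants(
        kdiss_r=kdiss_from_koff(koff_r, kout, kg_r),
        kdiss_t=kdiss_from_koff(koff_t, kout, kg_t),
        **rates,
    )
    return VariantData(rc, koff_slow, koff_fast, amp_slow, amp_fast)


#: Representative microscopic rate constants for MaPgb* (Cys101Ser reference
#: protein, "wt") and its distal-pocket / tunnel mutants at 20 C, with the
#: stopped-flow off-rates used to pin kdiss_r/kdiss_t.  The slower dissociation
#: phase is assigned to the r pathway (majority amplitude; the liganded
#: equilibrium favors r).
PRESETS: dict[str, VariantData] = {
    "wt": _variant(
        0.032, 0.081, 0.67, 0.33,
        k1=1.3e5, k_1=5e5, k3=6e4, k_3=2e4,
        kin_r=7.8e7, kin_t=3.0e7, kout=1.5e8,
        kg_r=5e7, kg_t=6.0e6,
        kc=1.0e7, k_c=1.0e7, kd2=1.0e7, k_d2=1.0e7,
    ),
    "trp60ala": _variant(
        0.020, None, 1.0, 0.0,
        k1=1.4e5, k_1=2e5, k3=5e3, k_3=9e3,
        kin_r=4.0e8, kin_t=3.0e7, kout=2.0e8,
        kg_r=5e7, kg_t=5e6,
        kc=5e7, k_c=5e7, kd2=5e7, k_d2=5e7,
    ),
    "phe93tyr": _variant(
        0.020, 0.24, 0.24, 0.76,
        k1=1.4e5, k_1=3e5, k3=1.5e5, k_3=2e4,
        kin_r=3.8e8, kin_t=3.0e7, kout=1.4e8,
        kg_r=2e7, kg_t=6e6,
        kc=5e7, k_c=1e7, kd2=5e7, k_d2=1.0e7,
    ),
    "phe93ala": _variant(
        0.21, 0.40, 0.66, 0.34,
        k1=1.35e5, k_1=8e4, k3=4e4, k_3=1.7e4,
        kin_r=3.7e8, kin_t=1.0e7, kout=7e7,
        kg_r=5e7, kg_t=6e6,
        kc=1.0e7, k_c=1e7, kd2=1e7, k_d2=1.0e7,
    ),
    "tyr61ala": _variant(
        0.050, 0.23, 0.68, 0.32,
        k1=1.35e5, k_1=4e5, k3=6e3, k_3=6e3,
        kin_r=7.0e8, kin_t=3e6, kout=4.5e8,
        kg_r=6e7, kg_t=6.0e6,
        kc=1.0e7, k_c=1e7, kd2=1e7, k_d2=1.0e7,
    ),
    "phe145trp": _variant(
        0.100, 0.50, 0.67, 0.33,
        k1=1.35e5, k_1=5e5, k3=4e4, k_3=1.7e4,
        kin_r=3.5e8, kin_t=3.0e7, kout=9e7,
        kg_r=4e7, kg_t=5e6,
        kc=7e6, k_c=3e7, kd2=7e6, k_d2=3e7,
    ),
}


def preset(name: str) -> RateConstants:
    """Rate constants for a named protein variant (see :data:`PRESETS`)."""
    try:
        return PRESETS[name].rates
    except KeyError:
        raise KeyError(
            f"unknown variant {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
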