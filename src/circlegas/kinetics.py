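"""Well-mixed gas kinetics of an anesthesia circle breathing system.

The circle system of a fresh-gas-decoupled (FGD) anesthesia workstation is
treated as a single well-mixed compartment of total gas volume ``V_tot``.
Fresh gas enters at a set flow and composition, the patient removes oxygen
(and optionally volatile agent and nitrous oxide) at constant rates, the
CO2 absorber is ideal, and surplus gas is vented at the circuit's own
composition so the compartment volume stays constant.  Each inspired-gas
fraction then relaxes exponentially toward a flow-weighted steady state:

    F_circ(t) = F_circ(0) + (F_del - F_circ(0)) * (1 - exp(-t / tau))

with tau = V_tot / FGF for an uptake-free circuit, or more generally
tau = V_S / (Vdot_D - Vdot_uptake) when gas is taken up from the system
(the Conway form).

Disconnecting the reservoir bag opens the bag port to the atmosphere.  The
leak is lumped into two parameters: ``fgf_retained_fraction`` (how much of
the fresh gas still sweeps the circuit rather than escaping through the
open port) and ``entrain_flow`` (room air drawn in through the port, 21 %
O2 / 79 % N2).  Both appear in :class:`CircuitConfig` and both are plain
numbers a user can override; the defaults are a calibration discussed in
``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical gas ordering used by every array in the package.
GASES = ("o2", "sevo", "n2o", "co2", "n2")
_IDX = {g: i for i, g in enumerate(GASES)}

#: Room air as a dry-gas mixture (argon etc. folded into N2).
ROOM_AIR_FRACTIONS = np.array([0.21, 0.0, 0.0, 0.0, 0.79])

_SUM_TOL = 1e-9


class ConfigurationError(ValueError):
    """A circuit/fresh-gas/patient configuration is physically inconsistent."""


class StepSizeError(RuntimeError):
    """An integration step drove a gas fraction negative; reduce dt."""


@dataclass(frozen=True)
class GasComposition:
    """Fractions of O2, sevoflurane, N2O, CO2 and N2 summing to one.

    All fractions are dimensionless in [0, 1].  ``fn2`` is the balance gas
    and normally absorbs rounding residue when a mixture is specified in
    percent (see :meth:`from_delivery`).
    """

    fo2: float
    fsevo: float = 0.0
    fn2o: float = 0.0
    fco2: float = 0.0
    fn2: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.fo2, self.fsevo, self.fn2o, self.fco2, self.fn2)
        for name, v in zip(GASES, vals):
            if v < -1e-12:
                raise ValueError(f"negative gas fraction {name}={v}")
            if v < 0.0:  # clamp float dust
                object.__setattr__(self, "f" + name if name != "sevo" else "fsevo", 0.0)
        if abs(sum(vals) - 1.0) > _SUM_TOL:
            raise ValueError(f"gas fractions sum to {sum(vals)!r}, not 1")

    # -- constructors -------------------------------------------------
    @classmethod
    def room_air(cls) -> "GasComposition":
        return cls(fo2=0.21, fn2=0.79)

    @classmethod
    def pure_oxygen(cls) -> "GasComposition":
        return cls(fo2=1.0)

    @classmethod
    def from_delivery(
        cls, o2_pct: float, sevo_vol_pct: float = 0.0, balance: str = "n2"
    ) -> "GasComposition":
        """Build a delivered mixture from rotameter/vaporizer settings.

        ``o2_pct`` and ``sevo_vol_pct`` are divided by 100; the remainder
        goes to the balance gas (``"n2"`` for an O2/air carrier, ``"n2o"``
        for an O2/N2O carrier), which absorbs any rounding residue.
        """
        fo2 = o2_pct / 100.0
        fsevo = sevo_vol_pct / 100.0
        rest = 1.0 - fo2 - fsevo
        if rest < -1e-12:
            raise ValueError("O2 and vapor percentages exceed 100 %")
        rest = max(rest, 0.0)
        if balance == "n2":
            return cls(fo2=fo2, fsevo=fsevo, fn2=rest)
        if balance == "n2o":
            return cls(fo2=fo2, fsevo=fsevo, fn2o=rest)
        raise ValueError(f"unknown balance gas {balance!r}")

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "GasComposition":
        return cls(*(float(x) for x in arr))

    # -- accessors ----------------------------------------------------
    def as_array(self) -> np.ndarray:
        return np.array([self.fo2, self.fsevo, self.fn2o, self.fco2, self.fn2])

    def fraction(self, gas: str) -> float:
        try:
            return self.as_array()[_IDX[gas]]
        except KeyError:
            raise ValueError(f"unknown gas {gas!r}; expected one of {GASES}") from None


@dataclass(frozen=True)
class CircuitConfig:
    """Circle-system volumes and the lumped bag-port leak model.

    Volumes in litres.  ``v_internal`` is the workstation's internal gas
    volume including its default refillable absorber of volume
    ``v_absorber_default``; if a different absorber of volume
    ``v_absorber_used`` is fitted, the total swaps one for the other and
    adds the breathing-hose volume ``v_hose``:

        v_tot = v_internal - v_absorber_default + v_absorber_used + v_hose

    ``bag_connected`` toggles the bag-port leak: when False, only
    ``fgf_retained_fraction`` of the fresh gas still reaches the circuit
    and ``entrain_flow`` L/min of room air is drawn in through the open
    port.
    """

    v_internal: float = 4.7
    v_absorber_default: float = 1.5
    v_absorber_used: float = 1.2
    v_hose: float = 1.2
    bag_connected: bool = True
    entrain_flow: float = 1.7
    fgf_retained_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.v_internal <= 0 or self.v_absorber_default <= 0:
            raise ConfigurationError("workstation and absorber volumes must be > 0")
        if self.v_absorber_used < 0 or self.v_hose < 0:
            raise ConfigurationError("fitted absorber and hose volumes must be >= 0")
        if self.entrain_flow < 0:
            raise ConfigurationError("entrain_flow must be >= 0")
        if not 0.0 <= self.fgf_retained_fraction <= 1.0:
            raise ConfigurationError("fgf_retained_fraction must be in [0, 1]")
        if self.v_tot <= 0:
            raise ConfigurationError(
                f"derived total volume {self.v_tot:.3f} L is not positive"
            )

    @property
    def v_tot(self) -> float:
        return (
            self.v_internal
            - self.v_absorber_default
            + self.v_absorber_used
            + self.v_hose
        )


@dataclass(frozen=True)
class FreshGasSettings:
    """Fresh gas flow (L/min) and its delivered composition."""

    fgf: float
    delivered: GasComposition

    def __post_init__(self) -> None:
        if self.fgf < 0:
            raise ConfigurationError("fgf must be >= 0")


@dataclass(frozen=True)
class PatientModel:
    """Constant-rate gas exchange of the (simulated) patient.

    Rates in mL/min: ``vo2`` oxygen consumption, ``vco2`` CO2 production
    (removed by the ideal absorber, so it never appears in inspired gas),
    ``sevo_uptake``/``n2o_uptake`` agent uptake from the circuit.  ``frc``
    (L) optionally lumps the patient's functional residual capacity into
    the mixed volume; default 0 keeps the circuit-only volume.
    """

    vo2: float = 250.0
    vco2: float = 200.0
    sevo_uptake: float = 0.0
    n2o_uptake: float = 0.0
    frc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("vo2", "vco2", "sevo_uptake", "n2o_uptake", "frc"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def uptake_array_l_min(self) -> np.ndarray:
        """Per-gas uptake rates in L/min, package gas order."""
        return np.array(
            [self.vo2, self.sevo_uptake, self.n2o_uptake, 0.0, 0.0]
        ) / 1000.0


@dataclass(frozen=True)
class CircuitState:
    """Circuit composition at time ``t`` (minutes)."""

    t: float
    comp: GasComposition


# ---------------------------------------------------------------------
# Closed-form kinetics
# ---------------------------------------------------------------------

def total_volume(config: CircuitConfig) -> float:
    """Total mixed gas volume of the circle system, litres."""
    return config.v_tot


def wash_in_fraction(f0: float, f_del: float, t: float, tau: float) -> float:
    """Exponential wash-in/wash-out of a well-mixed circuit.

    Returns F_circ(t) = f0 + (f_del - f0) * (1 - exp(-t/tau)); the result
    always lies between ``f0`` and ``f_del``.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return f0 + (f_del - f0) * (1.0 - math.exp(-t / tau))


def tau_simple(v_tot: float, fgf: float) -> float:
    """Time constant of an uptake-free circuit: tau = V_tot / FGF (min)."""
    if fgf <= 0:
        raise ValueError(f"fgf must be > 0, got {fgf}")
    if v_tot <= 0:
        raise ValueError(f"v_tot must be > 0, got {v_tot}")
    return v_tot / fgf


def tau_conway(v_s: float, vd_dot: float, vuptake_dot: float = 0.0) -> float:
    """Uptake-corrected time constant tau = V_S / (Vdot_D - Vdot_uptake).

    ``v_s`` is the system volume (L), ``vd_dot`` the delivery rate and
    ``vuptake_dot`` the constant uptake rate (both L/min).  Reduces to
    :func:`tau_simple` when uptake is zero.
    """
    if vuptake_dot < 0:
        raise ValueError("vuptake_dot must be >= 0")
    if vd_dot <= vuptake_dot:
        raise ValueError(
            "delivery must exceed uptake for a finite time constant "
            f"(vd_dot={vd_dot}, vuptake_dot={vuptake_dot})"
        )
    if v_s <= 0:
        raise ValueError("v_s must be > 0")
    return v_s / (vd_dot - vuptake_dot)


def oxygen_delivery_ml_min(fg: FreshGasSettings) -> float:
    """Oxygen delivered to the circuit in mL/min (FGF x delivered FO2)."""
    return fg.fgf * fg.delivered.fo2 * 1000.0


# ---------------------------------------------------------------------
# Numerical mass balance
# ---------------------------------------------------------------------

def _balance_terms(
    config: CircuitConfig, fg: FreshGasSettings, patient: PatientModel
) -> tuple[float, np.ndarray, float]:
    """Effective volume, net per-gas source rates (L/min) and vent flow.

    CO2 produced by the patient is removed by the ideal absorber within
    the same instant, so it cancels out of both the source vector and the
    volume budget.
    """
    v_eff = config.v_tot + patient.frc
    if config.bag_connected:
        q_fresh, q_ent = fg.fgf, 0.0
    else:
        q_fresh = fg.fgf * config.fgf_retained_fraction
        q_ent = config.entrain_flow
    source = q_fresh * fg.delivered.as_array() + q_ent * ROOM_AIR_FRACTIONS
    uptake = patient.uptake_array_l_min()
    q_vent = q_fresh + q_ent - uptake.sum()
    if q_vent < 0:
        raise ConfigurationError(
            "patient uptake exceeds total gas inflow; the circuit volume "
            "cannot be conserved"
        )
    return v_eff, source - uptake, q_vent


def _advance(
    f: np.ndarray,
    n_steps: int,
    dt: float,
    v_eff: float,
    net_source: np.ndarray,
    q_vent: float,
) -> np.ndarray:
    """Explicit fixed-step update of the fraction vector, renormalized."""
    scale = dt / v_eff
    for _ in range(n_steps):
        f = f + scale * (net_source - q_vent * f)
    if f.min() < -1e-9:
        raise StepSizeError(
            f"gas fraction driven to {f.min():.3e} < 0; reduce dt "
            "(uptake outpaced mixing at this step size)"
        )
    f = np.clip(f, 0.0, None)
    return f / f.sum()


def step(
    state: CircuitState,
    dt: float,
    config: CircuitConfig,
    fg: FreshGasSettings,
    patient: PatientModel,
) -> CircuitState:
    """Advance the circuit composition by one explicit step of ``dt`` min.

    Volumetric balance over dt: fresh gas (reduced to the retained
    fraction when the bag is disconnected) plus entrained room air flow
    in; patient uptake removes pure O2 / agent; CO2 is produced and fully
    absorbed; the surplus is vented at circuit composition so volume is
    conserved.  The returned composition is renormalized to sum to one.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    v_eff, net_source, q_vent = _balance_terms(config, fg, patient)
    f = _advance(state.comp.as_array(), 1, dt, v_eff, net_source, q_vent)
    return CircuitState(t=state.t + dt, comp=GasComposition.from_array(f))
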