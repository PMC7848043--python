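"""Six-phase reservoir-bag-disconnection protocol and trace generation.

The canonical bench protocol runs, in order: room-air breathing (5 min),
preoxygenation (3 min, 100 % O2 at 6 L/min), an initial high-flow
anesthesia phase (10 min), maintenance at the study FGF (20 min), bag
disconnection (10 min) and bag reconnection (20 min) -- 68 min in total.
Maintenance, disconnection and reconnection share identical fresh-gas
settings; only the bag state differs.  Two carrier-gas scenarios are
supported (O2/air and O2/N2O) with the standard minimal-flow induction
and maintenance mixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .kinetics import (
    GASES,
    _IDX,
    CircuitConfig,
    CircuitState,
    FreshGasSettings,
    GasComposition,
    PatientModel,
    _advance,
    _balance_terms,
)

CARRIERS = ("oxygen_air", "oxygen_n2o")
CANONICAL_FGFS = (0.5, 1.0, 2.0)
PHASE_NAMES = (
    "room_air",
    "preoxygenation",
    "initial",
    "maintenance",
    "disconnected",
    "reconnected",
)
CANONICAL_DURATIONS = (5.0, 3.0, 10.0, 20.0, 10.0, 20.0)

#: Default integration step (min): 1/240 min = 0.25 s.
DEFAULT_DT = 1.0 / 240.0
#: Default monitor sampling interval (min): one reading per breath at
#: 12 breaths/min, i.e. 5 s.
DEFAULT_SAMPLE_INTERVAL = 1.0 / 12.0

#: Ventilator settings of the bench protocol.  The continuous mixing model
#: uses them only to motivate the per-breath sampling cadence; they are
#: carried for documentation and future breath-resolved extensions.
VENTILATOR_SETTINGS = {
    "tidal_volume_ml": 500.0,
    "respiratory_rate_per_min": 12.0,
    "ie_ratio": "1:2",
    "inspiratory_pause_pct": 10.0,
    "peep_cmh2o": 0.0,
}


@dataclass(frozen=True)
class Phase:
    """One protocol phase: a name, a duration and fixed fresh-gas settings.

    ``ambient`` marks phases in which the patient is not yet connected to
    the circle system (room-air breathing): the sampled composition is
    then pinned to the delivered mixture instead of integrating the
    circuit mass balance.
    """

    name: str
    duration: float
    fg: FreshGasSettings
    bag_connected: bool = True
    ambient: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("phase duration must be > 0")


@dataclass(frozen=True)
class Protocol:
    phases: tuple[Phase, ...]
    carrier: str
    fgf_maintenance: float

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        n_open = sum(not p.bag_connected for p in self.phases)
        if n_open > 1:
            raise ValueError("at most one phase may have the bag disconnected")

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)

    def phase_start(self, name: str) -> float:
        """Start time (min) of the first phase with the given name."""
        t = 0.0
        for p in self.phases:
            if p.name == name:
                return t
            t += p.duration
        raise ValueError(f"protocol has no phase named {name!r}")


#: Carrier-specific delivered mixtures: (O2 %, sevo vol%, FGF L/min) for
#: the initial phase and (O2 %, sevo vol%) for maintenance.
_CARRIER_SETTINGS = {
    "oxygen_air": {
        "balance": "n2",
        "initial": (40.0, 3.5, 4.0),
        "maintenance": (68.0, 5.0),
    },
    "oxygen_n2o": {
        "balance": "n2o",
        "initial": (32.0, 2.0, 4.4),
        "maintenance": (60.0, 3.5),
    },
}


def canonical_protocol(carrier: str, fgf_maintenance: float) -> Protocol:
    """The six-phase bench protocol for one carrier gas and one FGF.

    Maintenance FGF is canonically 0.5, 1.0 or 2.0 L/min; other values
    are accepted with a warning.
    """
    if carrier not in _CARRIER_SETTINGS:
        raise ValueError(f"unknown carrier {carrier!r}; expected one of {CARRIERS}")
    if fgf_maintenance <= 0:
        raise ValueError("fgf_maintenance must be > 0")
    if not any(abs(fgf_maintenance - f) < 1e-12 for f in CANONICAL_FGFS):
        warnings.warn(
            f"FGF {fgf_maintenance} L/min is outside the canonical set "
            f"{CANONICAL_FGFS}; proceeding anyway",
            stacklevel=2,
        )
    cs = _CARRIER_SETTINGS[carrier]
    o2_i, sevo_i, fgf_i = cs["initial"]
    o2_m, sevo_m = cs["maintenance"]
    fg_room = FreshGasSettings(fgf=0.0, delivered=GasComposition.room_air())
    fg_preox = FreshGasSettings(fgf=6.0, delivered=GasComposition.pure_oxygen())
    fg_initial = FreshGasSettings(
        fgf=fgf_i, delivered=GasComposition.from_delivery(o2_i, sevo_i, cs["balance"])
    )
    fg_maint = FreshGasSettings(
        fgf=fgf_maintenance,
        delivered=GasComposition.from_delivery(o2_m, sevo_m, cs["balance"]),
    )
    phases = (
        Phase("room_air", 5.0, fg_room, ambient=True),
        Phase("preoxygenation", 3.0, fg_preox),
        Phase("initial", 10.0, fg_initial),
        Phase("maintenance", 20.0, fg_maint),
        Phase("disconnected", 10.0, fg_maint, bag_connected=False),
        Phase("reconnected", 20.0, fg_maint),
    )
    return Protocol(phases=phases, carrier=carrier, fgf_maintenance=fgf_maintenance)


@dataclass(frozen=True)
class GasTrace:
    """Inspired-fraction time series on a uniform grid.

    ``times`` in minutes, ``fractions`` of shape (n, 5) in package gas
    order, ``phases`` the phase label owning each sample (a boundary
    sample belongs to the phase that starts there).  ``quantized`` traces
    hold monitor readings and are exempt from the sum-to-one invariant.
    """

    times: np.ndarray
    fractions: np.ndarray
    phases: np.ndarray
    quantized: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        f = np.asarray(self.fractions, float)
        p = np.asarray(self.phases)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "phases", p)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("trace needs at least two samples")
        if f.shape != (len(t), len(GASES)):
            raise ValueError(f"fractions must have shape ({len(t)}, {len(GASES)})")
        if len(p) != len(t):
            raise ValueError("phase labels must match times")
        dts = np.diff(t)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("times must lie on a uniform grid")
        if not self.quantized:
            if f.min() < -1e-12:
                raise ValueError("negative gas fraction in trace")
            if np.abs(f.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError("trace compositions must sum to 1 within 1e-9")

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def column(self, gas: str) -> np.ndarray:
        if gas not in _IDX:
            raise ValueError(f"unknown gas {gas!r}; expected one of {GASES}")
        return self.fractions[:, _IDX[gas]]

    def index_at(self, t: float) -> int:
        """Index of the grid sample at time ``t`` (must lie on the grid)."""
        i = int(round((t - self.times[0]) / self.sample_interval))
        if i < 0 or i >= len(self.times) or abs(self.times[i] - t) > 1e-6:
            raise ValueError(f"time {t} min is not on the trace grid")
        return i

    def window(self, t0: float, t1: float) -> "GasTrace":
        """Sub-trace covering [t0, t1] (both endpoints on the grid)."""
        i0, i1 = self.index_at(t0), self.index_at(t1)
        if i1 <= i0:
            raise ValueError("empty window")
        sl = slice(i0, i1 + 1)
        return GasTrace(
            self.times[sl], self.fractions[sl], self.phases[sl], self.quantized
        )


def run_protocol(
    protocol: Protocol,
    config: CircuitConfig | None = None,
    patient: PatientModel | None = None,
    dt: float = DEFAULT_DT,
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
) -> GasTrace:
    """Deterministic simulation of a protocol, starting from room air.

    Settings switch instantaneously at phase boundaries; the bag state
    follows each phase.  One sample is stored every ``sample_interval``
    minutes (default: one per breath, 5 s); the mass balance is advanced
    with explicit sub-steps of ``dt``.
    """
    config = config if config is not None else CircuitConfig()
    patient = patient if patient is not None else PatientModel()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if sample_interval < dt - 1e-12:
        raise ValueError("sample_interval must be >= dt")
    substeps = max(1, int(round(sample_interval / dt)))
    sub_dt = sample_interval / substeps

    f = GasComposition.room_air().as_array()
    times = [0.0]
    fracs = [f]
    labels = [protocol.phases[0].name]
    t0 = 0.0
    for k, phase in enumerate(protocol.phases):
        n_samp = int(round(phase.duration / sample_interval))
        if abs(n_samp * sample_interval - phase.duration) > 1e-9 or n_samp < 1:
            raise ValueError(
                f"phase {phase.name!r} duration {phase.duration} min is not a "
                f"multiple of the sample interval {sample_interval} min"
            )
        if phase.ambient:
            f = phase.fg.delivered.as_array()
            terms = None
        else:
            cfg = replace(config, bag_connected=phase.bag_connected)
            terms = _balance_terms(cfg, phase.fg, patient)
        is_last_phase = k == len(protocol.phases) - 1
        for i in range(n_samp):
            if terms is not None:
                f = _advance(f, substeps, sub_dt, *terms)
            t = t0 + (i + 1) * sample_interval
            # A boundary sample belongs to the phase that starts there.
            at_boundary = i == n_samp - 1 and not is_last_phase
            times.append(t)
            fracs.append(f)
            labels.append(protocol.phases[k + 1].name if at_boundary else phase.name)
        t0 += phase.duration
    return GasTrace(
        times=np.array(times),
        fractions=np.vstack(fracs),
        phases=np.array(labels, dtype=object),
    )
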