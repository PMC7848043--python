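"""Monitor-like synthetic replicate traces: noise plus quantization.

A sidestream gas monitor reports inspired fractions on a coarse grid --
whole percent for O2 and N2O, 0.1 vol% for sevoflurane -- with a little
reading-to-reading scatter.  This module layers that observation model on
top of the deterministic circuit simulation so the whole analysis pipeline
(window summaries, Friedman comparison, time-constant estimation) can be
exercised on replicate data with the bench study's structure: one shared
underlying trajectory, independent noise streams per replicate, three
replicates per condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import CircuitConfig, PatientModel, wash_in_fraction
from .scenario import (
    DEFAULT_DT,
    DEFAULT_SAMPLE_INTERVAL,
    GasTrace,
    Protocol,
    run_protocol,
)


@dataclass(frozen=True)
class MonitorModel:
    """Observation model of the gas monitor.

    ``noise_sd`` is the additive Gaussian reading noise in absolute %
    (applied before quantization); ``quant_*`` are the reporting steps in
    % (vol% for sevoflurane); ``sample_interval`` is the reading cadence
    in minutes (default one per breath, 5 s).  ``seed`` feeds every noise
    stream; per-replicate streams are derived from it with fixed offsets.
    """

    noise_sd: float = 0.5
    quant_o2: float = 1.0
    quant_n2o: float = 1.0
    quant_sevo: float = 0.1
    quant_co2: float = 0.1
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("quant_o2", "quant_n2o", "quant_sevo", "quant_co2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")

    def steps(self) -> np.ndarray:
        """Per-gas quantization steps in package gas order (N2 unreported,
        kept at fine resolution)."""
        return np.array(
            [self.quant_o2, self.quant_sevo, self.quant_n2o, self.quant_co2, 1e-6]
        )

    def rng_for_replicate(self, replicate: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, replicate])


def quantize(
    trace: GasTrace,
    monitor: MonitorModel,
    rng: np.random.Generator | None = None,
) -> GasTrace:
    """Turn a simulated trace into monitor readings.

    Each gas reading gets independent Gaussian noise (sd ``noise_sd`` %),
    is rounded to its reporting step and clamped to [0, 100] %.  N2 is not
    reported by the monitor and is recomputed as the clamped balance.
    Deterministic for a given generator state.
    """
    if rng is None:
        rng = monitor.rng_for_replicate(0)
    pct = trace.fractions * 100.0
    steps = monitor.steps()
    out = np.empty_like(pct)
    for j in range(4):  # o2, sevo, n2o, co2 -- the reported channels
        col = pct[:, j]
        if monitor.noise_sd > 0:
            col = col + rng.normal(0.0, monitor.noise_sd, size=col.shape)
        out[:, j] = np.clip(np.round(col / steps[j]) * steps[j], 0.0, 100.0)
    out[:, 4] = np.clip(100.0 - out[:, :4].sum(axis=1), 0.0, 100.0)
    return GasTrace(
        times=trace.times.copy(),
        fractions=out / 100.0,
        phases=trace.phases.copy(),
        quantized=True,
    )


def generate_replicates(
    protocol: Protocol,
    config: CircuitConfig | None = None,
    patient: PatientModel | None = None,
    monitor: MonitorModel | None = None,
    n_reps: int = 3,
    dt: float = DEFAULT_DT,
    base_trace: GasTrace | None = None,
) -> list[GasTrace]:
    """Replicate monitor traces of one protocol run.

    The deterministic trajectory is simulated once and shared; each
    replicate applies an independent noise stream (seed offsets 0..n-1)
    before quantization.  With three replicates, the per-minute readings
    of each 10-min analysis window pool to 30 values.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    monitor = monitor if monitor is not None else MonitorModel()
    if base_trace is None:
        base_trace = run_protocol(
            protocol,
            config=config,
            patient=patient,
            dt=dt,
            sample_interval=monitor.sample_interval,
        )
    return [
        quantize(base_trace, monitor, rng=monitor.rng_for_replicate(r))
        for r in range(n_reps)
    ]


def synthetic_exponential_trace(
    f0_pct: float,
    f_final_pct: float,
    tau: float,
    duration: float = 10.0,
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
    gas: str = "o2",
) -> GasTrace:
    """A pure single-exponential transient with known time constant.

    Injects ``wash_in_fraction`` dynamics for one gas (balance N2) on a
    uniform grid -- an oracle fixture for the 63 %-criterion estimator.
    """
    if gas == "n2":
        raise ValueError("the balance gas cannot carry the transient")
    n = int(round(duration / sample_interval))
    times = np.arange(n + 1) * sample_interval
    vals = np.array(
        [wash_in_fraction(f0_pct / 100.0, f_final_pct / 100.0, t, tau) for t in times]
    )
    from .kinetics import _IDX

    fractions = np.zeros((n + 1, 5))
    fractions[:, _IDX[gas]] = vals
    fractions[:, _IDX["n2"]] = 1.0 - vals
    phases = np.array(["disconnected"] * (n + 1), dtype=object)
    return GasTrace(times=times, fractions=fractions, phases=phases)
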