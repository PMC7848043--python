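"""Condition-level analysis and the reference-comparison report.

`analyze_condition` runs one carrier/FGF condition end to end: simulate
the six-phase protocol, generate replicate monitor traces, pool the
per-minute window readings (3 replicates x 10 readings = 30 values per
window), run the Friedman before/during/after comparison, and estimate
the disconnection time constant per replicate.  `reproduce_tables`
assembles the six canonical conditions into summary/tau tables and a
comparison against the bundled hardware reference measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .estimators import (
    FriedmanResult,
    WindowSummary,
    WINDOW_NAMES,
    disconnect_time,
    estimate_tau_63,
    friedman_test,
    per_minute_readings,
)
from .kinetics import CircuitConfig, PatientModel
from .scenario import (
    CANONICAL_FGFS,
    CARRIERS,
    DEFAULT_DT,
    GasTrace,
    canonical_protocol,
    run_protocol,
)
from .synthetic import MonitorModel, generate_replicates

#: Gases the monitor record is analyzed for, per carrier scenario.
GASES_BY_CARRIER = {
    "oxygen_air": ("o2", "sevo"),
    "oxygen_n2o": ("o2", "sevo", "n2o"),
}

#: Reporting resolution for time constants, minutes.
TAU_DECIMALS = 1


@dataclass(frozen=True)
class ConditionReport:
    """All analysis outputs of one carrier/FGF condition."""

    carrier: str
    fgf: float
    summaries: dict  # gas -> window -> WindowSummary (pooled, n=30)
    friedman: dict  # gas -> FriedmanResult
    tau_replicates: dict  # gas -> list of per-replicate tau (min)
    tau_deterministic: dict  # gas -> tau from the noise-free trace (min)
    base_trace: GasTrace
    replicates: list


def analyze_condition(
    carrier: str,
    fgf: float,
    config: CircuitConfig | None = None,
    patient: PatientModel | None = None,
    monitor: MonitorModel | None = None,
    n_reps: int = 3,
    dt: float = DEFAULT_DT,
) -> ConditionReport:
    """Full analysis pipeline for one canonical condition."""
    monitor = monitor if monitor is not None else MonitorModel()
    protocol = canonical_protocol(carrier, fgf)
    base = run_protocol(
        protocol, config=config, patient=patient, dt=dt,
        sample_interval=monitor.sample_interval,
    )
    reps = generate_replicates(
        protocol, config=config, patient=patient, monitor=monitor,
        n_reps=n_reps, dt=dt, base_trace=base,
    )
    t_disc = disconnect_time(base)
    tau_window = (t_disc, t_disc + 10.0)
    summaries: dict = {}
    friedman: dict = {}
    tau_reps: dict = {}
    tau_det: dict = {}
    for gas in GASES_BY_CARRIER[carrier]:
        pooled = {
            w: np.concatenate(
                [per_minute_readings(r, gas, w, t_disc) for r in reps]
            )
            for w in WINDOW_NAMES
        }
        summaries[gas] = {
            w: WindowSummary.from_values(pooled[w], gas=gas, window=w)
            for w in WINDOW_NAMES
        }
        # Paired blocks: one row per (replicate, minute) reading triple.
        matrix = np.column_stack([pooled[w] for w in WINDOW_NAMES])
        friedman[gas] = friedman_test(matrix)
        tau_reps[gas] = [
            estimate_tau_63(r, gas, tau_window).tau for r in reps
        ]
        tau_det[gas] = estimate_tau_63(base, gas, tau_window).tau
    return ConditionReport(
        carrier=carrier,
        fgf=fgf,
        summaries=summaries,
        friedman=friedman,
        tau_replicates=tau_reps,
        tau_deterministic=tau_det,
        base_trace=base,
        replicates=reps,
    )


def load_reference_tables() -> dict:
    """Bundled hardware reference summaries and time constants."""
    text = (
        resources.files("circlegas")
        .joinpath("data/reference_bench_tables.json")
        .read_text()
    )
    return json.loads(text)


def summary_frame(reports: list[ConditionReport]) -> pd.DataFrame:
    """Window-summary table (one row per carrier/gas/FGF/window)."""
    rows = []
    for rep in reports:
        for gas, by_window in rep.summaries.items():
            for w, s in by_window.items():
                rows.append(
                    {
                        "carrier": rep.carrier,
                        "gas": gas,
                        "fgf": rep.fgf,
                        "window": w,
                        "median": s.median,
                        "q25": s.q25,
                        "q75": s.q75,
                        "min": s.vmin,
                        "max": s.vmax,
                        "n": s.n,
                        "friedman_p": rep.friedman[gas].p_value,
                    }
                )
    return pd.DataFrame(rows)


def tau_frame(reports: list[ConditionReport]) -> pd.DataFrame:
    """Time-constant table (one row per carrier/gas/FGF), taus to 0.1 min."""
    rows = []
    for rep in reports:
        for gas, taus in rep.tau_replicates.items():
            q25, med, q75 = np.percentile(taus, [25, 50, 75])
            rows.append(
                {
                    "carrier": rep.carrier,
                    "gas": gas,
                    "fgf": rep.fgf,
                    "tau_median": round(float(med), TAU_DECIMALS),
                    "tau_q25": round(float(q25), TAU_DECIMALS),
                    "tau_q75": round(float(q75), TAU_DECIMALS),
                    "tau_deterministic": round(
                        rep.tau_deterministic[gas], TAU_DECIMALS
                    ),
                    "n_replicates": len(taus),
                }
            )
    return pd.DataFrame(rows)


def comparison_frame(reports: list[ConditionReport]) -> pd.DataFrame:
    """Simulated vs reference medians, with qualitative direction flags.

    The reference values are hardware measurements with an uncharacterized
    patient-simulator uptake model; the comparison therefore reports
    differences and trend agreement (did the disconnection lower the
    median, did it recover after reconnection) rather than asserting
    numerical equality.
    """
    ref = load_reference_tables()
    rows = []
    for rep in reports:
        fgf_key = f"{rep.fgf:.1f}"
        for gas, by_window in rep.summaries.items():
            ref_gas = ref["windows"][rep.carrier].get(gas)
            if ref_gas is None or fgf_key not in ref_gas:
                continue
            ref_w = ref_gas[fgf_key]
            sim_before = by_window["before"].median
            sim_during = by_window["during"].median
            sim_after = by_window["after"].median
            ref_before, ref_during, ref_after = (
                ref_w["before"][0],
                ref_w["during"][0],
                ref_w["after"][0],
            )
            rows.append(
                {
                    "carrier": rep.carrier,
                    "gas": gas,
                    "fgf": rep.fgf,
                    "sim_before": sim_before,
                    "ref_before": ref_before,
                    "sim_during": sim_during,
                    "ref_during": ref_during,
                    "sim_after": sim_after,
                    "ref_after": ref_after,
                    "diff_before": sim_before - ref_before,
                    "diff_during": sim_during - ref_during,
                    "diff_after": sim_after - ref_after,
                    "drop_direction_match": (sim_during < sim_before)
                    == (ref_during < ref_before),
                    "recovery_direction_match": (sim_after > sim_during)
                    == (ref_after > ref_during),
                }
            )
    return pd.DataFrame(rows)


def tau_comparison_frame(reports: list[ConditionReport]) -> pd.DataFrame:
    """Simulated vs reference disconnection time constants."""
    ref = load_reference_tables()
    rows = []
    for rep in reports:
        fgf_key = f"{rep.fgf:.1f}"
        for gas, taus in rep.tau_replicates.items():
            ref_gas = ref["tau"][rep.carrier].get(gas)
            if ref_gas is None or fgf_key not in ref_gas:
                continue
            sim_med = round(float(np.median(taus)), TAU_DECIMALS)
            rows.append(
                {
                    "carrier": rep.carrier,
                    "gas": gas,
                    "fgf": rep.fgf,
                    "sim_tau_median": sim_med,
                    "ref_tau_median": ref_gas[fgf_key][0],
                    "diff": sim_med - ref_gas[fgf_key][0],
                }
            )
    return pd.DataFrame(rows)


def reproduce_tables(
    seed: int = 0,
    config: CircuitConfig | None = None,
    patient: PatientModel | None = None,
    noise_sd: float = 0.5,
    n_reps: int = 3,
    dt: float = DEFAULT_DT,
) -> dict[str, pd.DataFrame]:
    """Run all six canonical conditions and build every report table.

    Returns a dict with ``summary`` (window medians/IQRs plus Friedman
    p-values for both carriers), ``tau`` (disconnection time constants),
    and ``comparison``/``tau_comparison`` against the bundled hardware
    reference.
    """
    reports = []
    for carrier in CARRIERS:
        for fgf in CANONICAL_FGFS:
            monitor = MonitorModel(noise_sd=noise_sd, seed=seed)
            reports.append(
                analyze_condition(
                    carrier,
                    fgf,
                    config=config,
                    patient=patient,
                    monitor=monitor,
                    n_reps=n_reps,
                    dt=dt,
                )
            )
    return {
        "summary": summary_frame(reports),
        "tau": tau_frame(reports),
        "comparison": comparison_frame(reports),
        "tau_comparison": tau_comparison_frame(reports),
    }
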