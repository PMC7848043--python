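# circlegas

Gas kinetics of an anesthesia circle breathing system with fresh-gas
decoupling (FGD), built to study what happens to inspired gases when the
reservoir bag is disconnected during mechanical ventilation.

In FGD workstations the fresh gas flow (FGF) is diverted into the
reservoir bag during inspiration, so the bag stays in-circuit even under
controlled ventilation — and removing it opens a leak through which room
air is entrained, diluting both the oxygen-enriched mixture and the
volatile agent. `circlegas` is aimed at anesthesia researchers and
educators who want to reproduce and explore that scenario quantitatively
without bench hardware: it couples a well-mixed single-compartment
simulator of the circle system to the standard analysis toolchain for
such experiments.

The core model is the exponential wash-in/wash-out of a well-mixed
circuit of total gas volume V_tot:

    F_circ(t) = F_circ(0) + (F_del − F_circ(0)) · (1 − e^(−t/τ)),
    τ = V_tot / FGF            (no uptake)
    τ = V_S / (V̇_D − V̇_uptake) (constant uptake, Conway form)

plus a lumped bag-port leak (retained fresh gas + continuous room-air
entrainment) for the disconnection phase. On top of the simulator sit the
analysis stages: per-minute window summaries (median [25th–75th
percentile], min, max) for the 10 min before/during/after disconnection,
the Friedman rank test across the paired windows, and the 63 %-criterion
time-constant estimator applied to the disconnection transient.

## Worked example

Theoretical circuit time constants for the 5.6 L circle system:

```
$ circlegas tau-theory --vtot 5.6 --fgf 0.5
tau = 11.2 min (V_tot=5.6 L, FGF=0.5 L/min)
```

(11.2, 5.6 and 2.8 min at FGF 0.5, 1 and 2 L/min — the pace at which the
intact circuit equilibrates toward the delivered mixture.)

Full analysis of one condition — O₂/air carrier, FGF 1 L/min, three
replicate monitor traces:

```
$ circlegas analyze --carrier oxygen_air --fgf 1.0 --seed 1
INFO resolved defaults: v_tot=5.60 L entrain_flow=1.70 L/min fgf_retained_fraction=1.00 dt=0.00417 min noise_sd=0.50% sample_interval=0.0833 min seed=1
   carrier  gas  fgf window  median    q25    q75  min  max  n   friedman_p
oxygen_air   o2  1.0 before   54.00 53.000 55.000 52.0 56.0 30 6.192048e-09
oxygen_air   o2  1.0 during   35.50 33.250 42.000 32.0 56.0 30 6.192048e-09
oxygen_air   o2  1.0  after   44.00 38.250 47.750 31.0 50.0 30 6.192048e-09
...
tau[o2]: median 2.4 min (replicates: 2.4, 2.4, 2.2)
```

Reading this: inspired O₂ sits near 54 % during maintenance, falls to a
median 35.5 % while the bag is off (room air entrainment), and climbs
back after reconnection; the before/during/after difference is highly
significant over the n = 30 paired per-minute readings (Friedman
p < 0.001), and the disconnection transient has a time constant of about
2.4 min — several times faster than the intact-circuit τ of 5.6 min at
this flow, which is exactly why an unnoticed bag disconnection is
dangerous: the protective oxygen reserve of the circuit erodes on a
time scale of a couple of minutes.

Other entry points: `circlegas simulate` (one deterministic run to CSV),
`circlegas generate` (replicate monitor traces), `circlegas estimate-tau`
(63 %-criterion τ from any trace CSV), and `circlegas reproduce-tables`
(all six carrier × FGF conditions, summary and τ tables, plus a
comparison against the bundled bench reference measurements). Everything
is also available as a library (`circlegas.run_protocol`,
`circlegas.analyze_condition`, ...), with YAML overrides for every
circuit/patient/monitor default via `--config`.

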