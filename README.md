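# daneuron

Models of how tonic AMPA- and NMDA-receptor co-activation shapes the
firing rate of midbrain dopaminergic (DA) neurons.

DA neurons pace-make at a few Hz through a subthreshold Ca²⁺–K⁺
oscillation: a voltage-gated Ca²⁺ current depolarizes the cell, calcium
accumulates, the SK-type Ca²⁺-activated K⁺ current repolarizes it, and
calcium is pumped back out.  Tonic NMDA-receptor drive — voltage-gated
through its Mg²⁺ block — can speed this oscillation up dramatically,
whereas the voltage-independent AMPA-receptor current mostly pushes the
cell into depolarization block.  Because both receptors are opened by
glutamate, the interesting regime is their *co-activation*: over part of
the `(g_AMPA, g_NMDA)` conductance plane the joint drive fires the neuron
faster than NMDA alone ever does, and outside that region it silences it.
This package quantifies that synergy and explains it geometrically.

## The two models

**Minimal model** — a planar FitzHugh–Nagumo-type oscillator (variables
`v`, `w`; dimensionless; `t` in seconds) in which the usual linear
recovery feedback is replaced by the SK nonlinearity:

    c v̇ = f(v) + g_KCa (E_K − v) w⁴/(w⁴ + k_Ca⁴) + j_stim(v)
    c ẇ = ε g(v, w)

with `f(v) = a₁(v³ + a₂v² + a₃v + a₄)`,
`j_stim = g_N/(1 + M e⁻⁶ᵛ) · (E_N − v) + g_A (E_A − v)`, and a
piecewise-linear `g(v, w)` whose upper branch (`w ≥ 0`) is `v − k_w`.
A spike is registered when `v` crosses −0.4 upward.

**Biophysical model** — a three-variable conductance-based cell
(`v` in mV, `Ca` in µM, ERG gating `n`; `t` in ms): an L-type Ca²⁺
current, SK, a slow ERG K⁺ current (`ḡ_ERG n⁴`), an instantaneous
depolarization-limiting K⁺ current, a leak, and tonic AMPA/NMDA
conductances with the standard `1/(1 + 0.1[Mg²⁺]e^(−0.062v))` block.
Calcium balances L-type influx against a linear pump, scaled by the
surface-to-volume ratio of a sphere and a buffering coefficient.  The
numeric parameter set is a versioned calibration config
(`src/daneuron/data/biophysical_calibration.toml`).  Spike threshold:
−40 mV.

Both models omit the fast spike-producing currents on purpose: in DA
neurons those ride on top of the subthreshold oscillation without
changing its period, so the threshold-crossing rate of the oscillation
*is* the firing rate.

## Worked example

Simulate the minimal model at its co-activation optimum:

```sh
$ daneuron simulate --model minimal --g-ampa 0.026 --g-nmda 0.77 --out-dir out/
regime: firing  frequency: 9.887 Hz
outputs in out/
```

The run writes `trajectory.csv`, `firing_summary.json`, a voltage-trace
figure, and the fully resolved `run_config.json`.  Compare the
unstimulated cell (`daneuron simulate --model minimal` → 1.215 Hz, the
tonic pacemaker rate) and NMDA alone (`--g-nmda 0.77` → 8.109 Hz): the
AMPA contribution on top of NMDA buys another ~20%.

The full plane, with the synergy summary:

```sh
$ daneuron sweep --model minimal --out-dir sweep/
NMDA-only max 8.25 Hz, joint max 9.92 Hz at (g_A=0.0235, g_N=0.7276): synergy 20.3%
```

`frequency_map.csv` holds the long-format map (conductances, frequency,
regime) and `synergy_report.json` the numbers above: the best frequency
reachable with NMDA alone, the global maximum under co-activation, its
location, and the percentage gain.  For the biophysical cell
(`--model biophysical`) the same sweep reports an NMDA-only maximum of
50.0 Hz and a joint maximum about twice that, at interior conductances.

Phase-plane geometry behind the effect (nullclines, equilibria, and the
oscillation-onset boundary where the stable equilibrium loses stability
through a supercritical Andronov–Hopf bifurcation):

```sh
$ daneuron phaseplane --model minimal --out-dir pp/
```

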