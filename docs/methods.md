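# Methods

## Modeling scope and assumptions

Both models describe the subthreshold Ca²⁺–K⁺ oscillator of a midbrain
dopaminergic neuron, not its spikes.  Fast Na⁺ and delayed-rectifier
currents are omitted; a spike is the event of the oscillation crossing a
threshold from below (−0.4 dimensionless / −40 mV), and the firing rate
is the steady-state rate of such crossings.  Synaptic receptors are
activated tonically: AMPA and NMDA conductances are constants (NMDA
voltage-gated by Mg²⁺ block) with no kinetic gating, which matches
stimulation protocols whose timescale is much longer than receptor
activation.  Consequences: no spike-frequency adaptation, no transient
(burst-onset) frequencies — all reported rates are attractor properties —
and no repetitive burst/pause patterning, which requires mechanisms
outside these models.

## Minimal model

State `(v, w)`: `v` plays membrane potential, `w` calcium concentration.
Parameters (dimensionless unless noted):

| symbol | default | meaning |
|---|---|---|
| c | 1.1e-4 | time calibration; makes `t` seconds and rates Hz |
| ε | 0.01 | slow-variable rate (calcium buffering) |
| a₁..a₄ | −1, 1.35, 0.54, 0.0539 | cubic coefficients of `f(v)` |
| g_KCa, E_K, k_Ca | 0.5, −1, 10 | SK conductance, K reversal, half-activation |
| k_w | −0.585 | recovery threshold; the w-nullcline voltage |
| M | 0.2 | Mg-block strength in `g_N(v) = g_N/(1+M e⁻⁶ᵛ)` |
| E_N, E_A | 0, 0 | synaptic reversals |
| g_A, g_N | control | AMPA / NMDA maximal conductances |

The recovery function is piecewise linear: `g = v − k_w` for `w ≥ 0` and
`g = 0.01(v − k_w) − w` for `w < 0`.  The branch variable is `w`: the
`−w` pullback below the axis prevents the mirrored (w < 0) branch of the
v-nullcline — the Hill term is even in `w` — from creating spurious
stable equilibria that would attract trajectories out of the oscillatory
region.  At exactly `w = 0` the upper branch applies, so `ẇ ≥ 0`
whenever `v ≥ k_w` there.  The Jacobian used for stability analysis
takes the same branch convention.

Observed attractor ranges with the default set: `v ∈ (−0.78, −0.15)`;
`w` travels roughly 1.4–10 across the sweeps, i.e. well above unity
(the Hill half-activation k_Ca = 10 forces this); the analysis windows
are sized accordingly.

Computed reference behavior (reproduced by the test suite and
`scripts/acceptance.py`): tonic 1.215 Hz with no input; NMDA-only curve
single-peaked with maximum 8.25 Hz near g_N ≈ 0.62; AMPA-only maximum
2.59 Hz with depolarization block from g_A ≈ 0.006; joint maximum
9.92 Hz at (g_A, g_N) ≈ (0.0235, 0.728), a 20.3% synergy over NMDA
alone.

**Known limitation — absolute frequency scale.**  The time-calibration
constant `c` fixes the absolute Hz scale of every rate in this model.
With the standard dimensionless set above, the stimulated maxima sit a
factor ~2.5 below the >20 Hz range often quoted for NMDA-driven DA-cell
firing, while every scale-free quantity (the 1–4 Hz tonic band via `c`,
the single-peaked NMDA response, the <10 Hz AMPA ceiling relative to
block, the ~20% co-activation synergy, and all phase-plane structure) is
reproduced.  A uniform rescaling `c → c/2.5` would move the NMDA-only
peak above 20 Hz at the cost of a ~3 Hz tonic rate; we keep the standard
set and report the frequencies it actually produces.  The frequency
ridge around the joint maximum is flat to <0.5% over g_N ∈ [0.68, 0.80],
so the argmax location is intrinsically ill-conditioned at that level.

## Biophysical model

State `(v, Ca, n)` in (mV, µM, –); time in ms.  Voltage equation
(µA/cm² with conductances in mS/cm²):

    c_m v̇ = g_Ca(v)(E_Ca − v)
            + (g_KCa(Ca) + ḡ_ERG n⁴ + g_K(v))(E_K − v)
            + g_l(E_l − v) + ḡ_AMPA(E_AMPA − v) + g_NMDA(v)(E_NMDA − v)

with `g_Ca = ḡ_Ca α⁴/(α+β)⁴`, `α = 0.0032(v+50)/(1 − e^(−(v+50)/5))`
(removable singularity at −50 mV evaluated by its limit),
`β = 0.05 e^(−(v+55)/40)`; SK `= ḡ_KCa Ca⁴/(Ca⁴ + k_Ca⁴)`;
`g_K = ḡ_K/(1 + e^(−(v+10)/7))` — the non-singular Boltzmann form, since
a `1 − e^...` denominator would diverge at −10 mV, impossible for a
current that limits depolarization; NMDA block
`1/(1 + 0.1·Mg·e^(−0.062v))`.  ERG gating relaxes to an increasing
sigmoid `n_∞(v)` (half −47.4 mV, slope 2 mV — ERG is
depolarization-activated) with
`τ_n = 62 + 300·(σ↓(v; −50.4) − σ↓(v; −63.4))` ms, a bump ≥ 62 ms
peaking near −57 mV.  Calcium:

    Ċa = (2β_buf/r)·( g_Ca(v)(E_Ca − v)/(zF) − P_Ca·Ca )

The `2β_buf/r` prefactor is the surface-to-volume reading (flux through
a sphere of radius r attenuated by instantaneous buffering); the
composite prefactor is a single field, and a `literal` mode (`2rβ`) can
be selected in the config without code change.  Unit bookkeeping
(µA/cm² → µM/ms with r in µm) is folded into one named constant.

### Calibration config

The cell's numeric parameters ship as
`src/daneuron/data/biophysical_calibration.toml`, the single source of
truth (dataclass defaults mirror it; a test keeps them equal).  The set
was calibrated, by direct search over (ḡ_Ca, ḡ_KCa, k_Ca, g_l, E_l,
P_Ca) with everything else fixed, to express the intended physiology:

- low-frequency pacemaking with no synaptic input (5.0 Hz);
- pacemaking persists with ḡ_KCa = 0 (4.35 Hz) — the ERG current at
  ḡ_ERG = 2 mS/cm² is the backup slow negative feedback;
- NMDA-only drive reaches a ~50 Hz maximum over ḡ_NMDA ∈ [0, 12];
- AMPA alone causes depolarization block at low conductance
  (≥ 0.05 mS/cm²) after only a modest rate increase;
- co-activation beats the NMDA-only maximum by well over 40%
  (computed: ~129% at the joint optimum near ḡ_AMPA ≈ 0.3, with the
  reference operating point (0.16, 8) firing at 66.9 Hz).

Choices a practitioner should know: E_Ca = 100 mV, E_K = −90 mV;
Mg = 2 mM, consistent with the minimal model's `M = 0.2 = 0.1·Mg`; the
leak reverses at a distinct E_l = −45 mV (it supplies the depolarizing
drift that carries the cell into the L-type activation range; tying the
leak to E_K instead abolishes pacemaking); r = 5 µm, β_buf = 0.05
(≈ 1:20 free-to-bound Ca), P_Ca = 0.28 µm/ms giving a ~180 ms calcium
relaxation time.

## Numerical methods

- **Integrator**: Dormand–Prince 5(4) with adaptive proportional step
  control, compiled with numba per model.  Defaults rtol 1e-8,
  atol 1e-10.  Output is sampled on a fixed grid (0.5 ms equivalent) by
  cubic Hermite interpolation between accepted steps, so no oscillation
  is skipped by large slow-branch steps.  Failure (non-finite state or
  step underflow) raises an error naming the first bad time.
- **Crossing detection**: upward crossing at sample pair `(i, i+1)` when
  `v_i ≤ θ < v_{i+1}`, located by linear interpolation; the convention
  guarantees alternation with downward crossings and counts a crossing
  that starts exactly at threshold.
- **Frequency**: `(count − 1)/(t_last − t_first)` over the post-transient
  window, requiring ≥ 3 crossings (conservative against edge effects);
  converted to Hz at this boundary.  Transient discard 10 s (minimal) /
  5 s (biophysical); default windows 20 s / 10 s, ≥ 10 periods of the
  slowest reported rhythm.  Halving both tolerances or doubling the
  window moves reported frequencies by < 1% (asserted in the suite).
- **Regimes**: `firing` (≥ 3 crossings), `subthreshold_oscillation` (no
  crossings but peak-to-trough voltage above a floor of 1% of the
  unstimulated threshold-to-trough excursion: 0.003 / 0.3 mV), else
  `quiescent`.  The floor separates Hopf-attenuated small cycles from
  true equilibria.
- **Default initial states**: (−0.7, 0.1) and (−60 mV, 0.1·k_Ca,
  n_∞(−60)).  No multistability was observed in the firing region; the
  suite checks insensitivity to a distant second initial state.
- **Sweeps**: every grid point is an independent simulation from the
  standard initial state (steady-response protocol).  Standard grids:
  minimal g_A ∈ [0, 0.06] step 0.002, g_N ∈ [0, 1.2] step 0.02;
  biophysical ḡ_AMPA ∈ [0, 0.4] step 0.02, ḡ_NMDA ∈ [0, 12] step 0.25
  (the test suite thins the biophysical grid 2× per axis; the acceptance
  script uses the full grids).  Map maxima are polished within their
  winning cell by two rounds of alternating 1-D golden-section searches,
  because a smooth flat peak exceeds any grid value slightly.
- **Equilibria and stability** (minimal model): equilibria with w ≥ 0
  sit on v = k_w, where the total current is strictly decreasing in w —
  one bracketed root, polished by Brent's method; w < 0 equilibria are
  scanned along the lower recovery branch.  Stability comes from the
  eigenvalues of the analytic Jacobian (branch rule as above).  The
  Hopf boundary is traced by bisecting the leading eigenvalue's real
  part in g_N per g_A column (tolerance 1e-4 in conductance, below the
  map's cell size); supercriticality is verified empirically by the
  continuous collapse of cycle amplitude at the boundary, not assumed
  from normal-form coefficients.  g_A levels whose boundary falls
  outside the scanned g_N range are omitted with a log notice.

## Known limitations

- The absolute frequency scale of the stimulated minimal model (see
  above); relative and geometric results are unaffected.
- The biophysical parameter set is a calibration artifact: it realizes
  the qualitative physiology stated above, but no claim is made that it
  matches any particular cell's measured conductance densities, and the
  synergy magnitude (~129%) depends on it.
- The conversion between a measured AMPA/NMDA *current* ratio and a
  conductance ratio line on the map is protocol-dependent and is not
  implemented; `ratio_line_profile` takes the conductance ratio as
  input.
- Phase-plane machinery (nullclines, Hopf tracing) covers only the
  planar minimal model; the 3-variable cell is analyzed by simulation.
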