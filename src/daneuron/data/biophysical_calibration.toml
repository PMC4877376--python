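# Calibration config of the biophysical dopaminergic-neuron model.
# This file is the single source of truth for the calibrated cell; the
# BioParams dataclass defaults mirror it and a unit test keeps them in sync.
#
# The cell is calibrated so that, with no synaptic input, the subthreshold
# Ca2+-K+ mechanism pace-makes at low frequency; pacemaking persists when
# the SK conductance is removed (the ERG current then provides the slow
# negative feedback); a tonic NMDA conductance sweep at zero AMPA reaches
# a maximum firing rate of ~50 Hz; and AMPA alone drives the cell into
# depolarization block at low conductance.
#
# Units: mV, ms, uM, mS/cm^2, uF/cm^2; radius in um, pump rate in um/ms.

[biophysical]
c_m = 1.0
gbar_ca = 0.8
e_ca = 100.0
gbar_kca = 12.0
k_ca = 0.8
gbar_erg = 2.0
gbar_k = 4.0
e_k = -90.0
g_l = 0.1
e_l = -45.0
gbar_ampa = 0.0
e_ampa = 0.0
gbar_nmda = 0.0
e_nmda = 0.0
mg = 2.0
radius_um = 5.0
beta_buf = 0.05
z_ca = 2.0
faraday = 96485.0
p_ca = 0.28
erg_v_half = -47.4
erg_slope = 2.0
erg_tau_base = 62.0
erg_tau_amp = 300.0
erg_tau_v1 = -50.4
erg_tau_v2 = -63.4
v_spike = -40.0
ca_prefactor_mode = "surface_to_volume"
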