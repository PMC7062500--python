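# Default membrane-mechanism parameters (single source of truth).
# Units are annotated in each key name: mV, ms, mM, S/cm2, mA/cm2, um.

ion_conditions:
  Ca_i_mM: 5.0e-5        # 50 nM resting intracellular Ca2+
  Na_i_mM: 10.0
  Ca_o_mM: 2.0
  Na_o_mM: 140.0
  temperature_K: 307.15  # 34 C, standard for hippocampal slice models

ncx:
  # Electrochemical/allosteric exchanger formulation (cardiac-style kinetics).
  Vmax_mA_cm2: 0.1       # maximal current density scale
  gamma: 0.35            # voltage-dependence partition
  ksat: 0.27             # saturation factor
  km_Na_mM: 87.5         # half-saturation for [Na+]o
  km_Ca_mM: 1.38         # half-saturation for [Ca2+]o
  Km_Ca_act_mM: 1.25e-4  # allosteric Ca activation half-max (125 nM)
  n_Hill: 2.0

kca:
  # Hill-type Ca2+-activated K+ conductance, m^2 gating.
  # alpha/beta give an SK-like EC50 of ~0.6 uM and tau ~15 ms at EC50,
  # appropriate for the sub-micromolar dendritic Ca transients of the
  # reduced model (see docs/methods.md).
  gbar_S_cm2: 0.003
  E_K_mV: -80.0
  n: 2
  alpha_per_mM2_ms: 9.2e4
  beta_per_ms: 0.033
  tau_min_ms: 0.1

ca_pool:
  # Submembrane shell with first-order extrusion (pump) back to rest.
  shell_depth_um: 0.1
  tau_decay_ms: 80.0
  Ca_rest_mM: 5.0e-5
  Ca_min_mM: 1.0e-6

channels:
  na:
    gbar_S_cm2: 0.12
    E_rev_mV: 50.0
  na_axon:
    gbar_S_cm2: 0.30
    E_rev_mV: 50.0
  na_dend:
    gbar_S_cm2: 0.03     # supports decremental backpropagation
    E_rev_mV: 50.0
  kdr:
    gbar_S_cm2: 0.036
    E_K_mV: -80.0
  kdr_dend:
    gbar_S_cm2: 0.012
    E_K_mV: -80.0
  ka:
    gbar_S_cm2: 0.002
    E_K_mV: -80.0
    # density grows linearly with path distance in the apical tree
    distal_factor: 3.0     # multiplier at max apical distance
  cal:
    gbar_S_cm2: 1.0e-4
    E_Ca_mV: 120.0         # fixed reversal; pool uses true concentrations

passive:
  Cm_uF_cm2: 1.0
  Ra_ohm_cm: 150.0
  g_leak_S_cm2: 2.5e-5
  E_leak_mV: -65.0

rate_scale: 1.0            # global multiplier on HH gating rates

# Wildtype spatial distribution of mechanisms by region.
distributions:
  na:      {regions: [soma]}
  na_axon: {regions: [axon]}
  na_dend: {regions: [apical_primary, apical_oblique, apical_tuft, basal]}
  kdr:     {regions: [soma, axon]}
  kdr_dend: {regions: [apical_primary, apical_oblique, apical_tuft, basal]}
  ka:      {regions: [apical_primary, apical_oblique, apical_tuft], model: linear_with_distance}
  cal:     {regions: [apical_primary, apical_oblique, apical_tuft]}
  kca:     {regions: [soma, apical_primary, apical_oblique, apical_tuft, basal]}
  ncx:     {regions: [soma, apical_primary, apical_oblique, apical_tuft, basal]}
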