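# Reference configuration for the astroca package.
#
# dkm_rates: per-site binding (1/(uM s)) and unbinding (1/s) rate constants of
# the eight-state IP3R subunit chain. Binding/unbinding at the IP3 site and the
# dominant inhibiting Ca site depend on the occupancy of the other site, as in
# the original receptor model; the activating Ca site is independent.
dkm_rates:
  ip3_site:
    on_inh_free: 400.0      # a1
    on_inh_bound: 400.0     # a3
    off_inh_free: 52.0      # b1 (Kd 0.13 uM)
    off_inh_bound: 377.36   # b3 (Kd 0.9434 uM)
  ca_inhibiting_site:
    on_ip3_bound: 0.2       # a2
    on_ip3_free: 0.2        # a4
    off_ip3_bound: 0.2098   # b2 (Kd 1.049 uM)
    off_ip3_free: 0.0289    # b4 (Kd 0.1445 uM)
  ca_activating_site:
    "on": 20.0              # a5
    "off": 1.6468           # b5 (Kd 0.08234 uM)

# physiology: linearized reaction-diffusion cell (units: uM, um, s)
physiology:
  radius_um: 10.0
  gamma: 5.0                # V_cyt / V_ER
  d_ca: 220.0               # um^2/s
  d_er: 70.0
  d_buffer: 95.0
  ca_rest: 0.055            # 55 nM
  er_rest: 800.0
  ip3: 80.0                 # as printed; far above receptor saturation, see docs
  buffer_total: 52.0        # mobile (EGTA-like)
  buffer_on: 0.3            # 1/(uM s)
  buffer_off: 1.5           # 1/s
  buffer_immobile_total: 30.0
  buffer_immobile_on: 600.0
  buffer_immobile_off: 100.0
  pump_rate: 86.0           # reference SERCA rate P_p, 1/s
  regularization_radius_um: 0.05
  local_peak_target_uM: 100.0

geometry:
  n_clusters: 31
  channels_min: 2
  channels_max: 16
  min_separation_um: 1.5
  placement_radius_fraction: 0.8
  seed: 2015

simulation:
  dt_macro_s: 0.001
  record_dt_s: 0.05
  l_max: 40
  kr_max: 60.0              # dimensionless k*R cutoff of the mode expansion
  seed: 1

# ode: well-stirred counter-model (units: uM, ms). Values as printed; see docs
# for the K_serca symbol collision and the inhibition-factor variants.
ode:
  P_r: 0.03
  p1: 0.5
  p2: 0.9
  p3: 1.3
  p4: 0.2
  P_p: 0.06
  p5: 10.0
  p6: 0.6
  p7: 1.0
  p8: 10.0
  p9: 0.2
  p10: 1.0
  p11: 1.0e-3
  p12: 3.0e-6
  p13: 15.0e-6
  p14: 0.01
  p15: 0.7
  IP3: 0.4
  f_cyt: 0.015
  f_er: 0.5
  J_ext_bas: 3.5e-3
  Delta: 0.07
  gamma_inv: 30.0
  K_serca: 0.2
  inhibition: printed       # printed | p4 | p3

# Corrected configuration in which the well-stirred model has a genuine
# oscillatory window in P_p (the printed configuration is non-oscillatory;
# see docs/methods.md).
ode_oscillatory:
  IP3: 2.0
  K_serca: 0.1
  inhibition: p3

detection:
  baseline_window_s: 60.0
  baseline_percentile: 10.0
  prominence_fraction: 0.2
  min_separation_s: 5.0
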