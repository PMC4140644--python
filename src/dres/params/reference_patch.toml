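# Frozen reference parameter set (calibrated once, version-controlled).
# A KLT + static-H membrane patch whose semi-infinite cable expresses a
# 308 -> 342 Hz transfer-resonance profile over the first 500 um.

[membrane]
c_m = 1.0      # uF/cm^2
g_l = 0.0      # mS/cm^2
e_l = -65.0    # mV
g_h = 0.3593   # mS/cm^2
e_h = -43.0    # mV

[membrane.klt]
gbar = 19.73148   # mS/cm^2
e_k = -90.0       # mV
p = 4
q = 1
w_half = -62.0    # mV (half-activation of w^p)
w_slope = 4.0     # mV
z_half = -71.0    # mV
z_slope = 10.0    # mV
z_floor = 0.5
tau_w_min = 0.15  # ms
tau_w_amp = 1.02863
tau_w_v0 = -60.0
tau_w_k1 = 6.0
tau_w_k2 = 45.0
tau_z_min = 8.48192   # ms; tau_z at rest = 12.732 ms (12.5 Hz corner)
tau_z_amp = 27.102
tau_z_v0 = -60.0
tau_z_k1 = 20.0
tau_z_k2 = 8.0
rate_scale = 1.0

[cable]
diam_um = 2.0
r_a = 150.0    # Ohm*cm
length_um = inf
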