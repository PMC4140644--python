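# Optimized-cable endpoint model: uniform high KLT density (15 mS/cm^2)
# with a linear H-conductance gradient raising the total leak from
# 0.32 to 1.0 mS/cm^2 distally; 200 um sealed cable.  Its transfer-
# impedance profile toward the proximal end spans 292 -> 325 Hz.

[membrane]
c_m = 1.0
g_l = 0.25
e_l = -75.35249
g_h = 0.07       # proximal; total leak g_l + g_h = 0.32
e_h = -43.0

[membrane.klt]
gbar = 15.0
e_k = -90.0
p = 4
q = 1
w_half = -62.0
w_slope = 4.0
z_half = -71.0
z_slope = 10.0
z_floor = 0.5
tau_w_min = 0.15
tau_w_amp = 1.02863
tau_w_v0 = -60.0
tau_w_k1 = 6.0
tau_w_k2 = 45.0
tau_z_min = 8.48192
tau_z_amp = 27.102
tau_z_v0 = -60.0
tau_z_k1 = 20.0
tau_z_k2 = 8.0
rate_scale = 1.0

[membrane_distal]
g_h = 0.75       # distal; total leak = 1.0

[cable]
diam_um = 3.9428572
r_a = 150.0
length_um = 200.0
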