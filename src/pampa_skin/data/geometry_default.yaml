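# Default PAMPA sandwich geometry.
# Units: volumes cm^3, area cm^2, times s, concentration mol·cm^-3.
V_D: 0.3            # donor well volume (300 µL)
V_A: 0.4            # acceptor well volume (400 µL)
A_filter: 0.28      # filter area
porosity: 0.7       # nominal filter porosity; effective area = A_filter * porosity
t_incubation: 25200 # 7 h incubation
tau_lag: 1200       # steady-state lag time (~20 min, unstirred plates)
C_D0_nominal: 1.0e-7  # nominal donor concentration (100 µM)
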