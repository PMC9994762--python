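# Nominal parameters for the minimal cascade model of the mitotic oscillator
# (Goldbeter, PNAS 88:9107-9111, 1991; cyclin C, cdc2 kinase fraction M,
# protease fraction X).  Units: concentrations in uM, rates in 1/min or
# uM/min; Michaelis constants K_1..K_4 are dimensionless fractions.
# V_M1 = 3 /min, V_M3 = 1 /min and K_c = 0.5 uM are folded into the model
# equations as fixed constants and are not scanned.
v_i = 0.025   # uM/min, constant cyclin synthesis rate
v_d = 0.25    # uM/min, maximum cyclin degradation rate by protease X
k_d = 0.01    # 1/min, first-order cyclin degradation rate
K_d = 0.02    # uM, Michaelis constant of cyclin degradation
K_1 = 0.005   # -, Michaelis constant, cdc2 activation
K_2 = 0.005   # -, Michaelis constant, cdc2 inactivation
K_3 = 0.005   # -, Michaelis constant, protease activation
K_4 = 0.005   # -, Michaelis constant, protease inactivation
V_2 = 1.5     # 1/min, maximum cdc2 inactivation rate
V_4 = 0.5     # 1/min, maximum protease inactivation rate
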