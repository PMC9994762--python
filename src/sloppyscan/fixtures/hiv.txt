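# Nominal parameters for the HIV infection model of CD4+ T cells
# (Perelson, Kirschner & De Boer, Math. Biosci. 114:81-125, 1993).
# States: uninfected T, latently infected T*, actively infected T**,
# free virus V.  Units: cells (or virions) per mm^3 and per day.
# T_max = 1500 /mm^3 is folded into the model equations as a fixed constant.
s    = 10.0      # cells/(mm^3 day), supply of CD4+ T cells from precursors
mu_T = 0.02      # 1/day, death rate of uninfected and latently infected T cells
r    = 0.03      # 1/day, growth rate of the CD4+ T cell population
k_1  = 2.4e-5    # mm^3/day, infection rate of CD4+ T cells by free virus
k_2  = 3.0e-3    # 1/day, latent -> actively infected conversion rate
mu_b = 0.24      # 1/day, death rate of actively infected T cells
N_v  = 1400.0    # virions/cell, free virus produced by lysing one infected cell
mu_v = 2.4       # 1/day, clearance rate of free virus
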