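# Mole-fraction solubility of decitabine (5-aza-2'-deoxycytidine,
# M = 228.21 g/mol) in supercritical CO2, measured gravimetrically on a
# 4-temperature x 8-pressure grid. Standard uncertainties:
# u(T) = 0.1 K, u(P) = 0.35 bar; u(y) per row below.
# Note: the u(y) printed for (308 K, 320 bar) is 5.81e-05 (~29% relative),
# an order of magnitude above every other row; it is transcribed as
# printed, not corrected.
temperature_K,pressure_bar,mole_fraction,u_mole_fraction
308,120,5.04e-05,4.51e-06
318,120,4.51e-05,3.86e-06
328,120,3.69e-05,2.66e-06
338,120,2.84e-05,2.35e-06
308,160,8.23e-05,6.55e-06
318,160,9.37e-05,6.90e-06
328,160,9.11e-05,7.79e-06
338,160,7.79e-05,6.26e-06
308,200,1.18e-04,6.14e-06
318,200,1.55e-04,1.21e-05
328,200,1.77e-04,1.27e-05
338,200,2.05e-04,1.43e-05
308,240,1.37e-04,1.72e-06
318,240,1.87e-04,9.45e-06
328,240,2.82e-04,1.63e-05
338,240,3.71e-04,1.71e-05
308,280,1.76e-04,1.20e-06
318,280,2.40e-04,8.49e-06
328,280,3.42e-04,2.00e-05
338,280,4.90e-04,2.27e-05
308,320,1.97e-04,5.81e-05
318,320,2.69e-04,2.85e-06
328,320,4.27e-04,7.82e-06
338,320,7.15e-04,1.06e-05
308,360,2.18e-04,8.39e-06
318,360,3.40e-04,2.71e-05
328,360,5.60e-04,1.82e-05
338,360,8.74e-04,2.06e-05
308,400,2.83e-04,7.17e-06
318,400,5.06e-04,4.13e-06
328,400,7.88e-04,1.06e-05
338,400,1.07e-03,1.20e-05
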