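# Measured printed line widths for 24.5 wt% Pluronic F-127 dispensed through
# blunt needles (21G/25G/27G, L = 0.005 m) on a pneumatic extrusion bioprinter.
# Full 3x3x3 factorial: pressure in multiples of 1e5 Pa, stage speed in m/s,
# width mean +/- sd in micrometres measured by optical microscopy.
# status: continuous | discontinuous (defect/droplet strand) | not_printed
# (pressure insufficient to dispense; width cells empty).
gauge,speed_m_s,pressure_1e5Pa,width_um,width_sd_um,status
21G,0.01,1,566.17,14,continuous
21G,0.01,2,2668.05,10,continuous
21G,0.01,3,3215.85,24,continuous
21G,0.02,1,368.75,7,discontinuous
21G,0.02,2,1771.66,30,continuous
21G,0.02,3,2237.90,20,continuous
21G,0.03,1,325.48,2,discontinuous
21G,0.03,2,1512.28,7,continuous
21G,0.03,3,1852.55,15,continuous
25G,0.01,1,,,not_printed
25G,0.01,2,325.06,17,discontinuous
25G,0.01,3,1447.95,1,continuous
25G,0.02,1,,,not_printed
25G,0.02,2,286.72,33,discontinuous
25G,0.02,3,527.68,19,discontinuous
25G,0.03,1,,,not_printed
25G,0.03,2,220.72,23,discontinuous
25G,0.03,3,406.20,13,discontinuous
27G,0.01,1,,,not_printed
27G,0.01,2,254.69,9,discontinuous
27G,0.01,3,435.47,7,discontinuous
27G,0.02,1,,,not_printed
27G,0.02,2,,,not_printed
27G,0.02,3,385.46,11,discontinuous
27G,0.03,1,,,not_printed
27G,0.03,2,,,not_printed
27G,0.03,3,281.86,18,discontinuous
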