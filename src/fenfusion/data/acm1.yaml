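# Aggregated canopy model (ACM-1) empirical coefficients.
#
# Coefficients are data, not code: substitute another calibrated vintage by
# pointing load_acm_constants() at a different file.  e1 is the canopy
# photosynthetic efficiency slot; it is calibrated per site (the c_eff process
# parameter) and therefore ships as null here.
name: acm1_default
e1: null          # canopy efficiency -- calibrated, see parameter registry
e2: 0.0156935     # day-length coefficient of the diurnal correction (h^-1)
e3: 4.22273       # CO2 compensation point of the internal-CO2 quadratic (ppm)
e4: 208.868       # CO2 half-saturation offset (ppm)
e5: 0.0453194     # intercept of the diurnal correction (dimensionless)
e6: 0.37836       # hydraulic-resistance coefficient of canopy conductance
e7: 7.19298       # asymptote of the light-limited efficiency e0 (gC m-2 d-1)
e8: 0.011136      # temperature coefficient of photosynthetic demand (degC^-1)
e9: 2.1001        # half-saturation of e0 in LAI^2 (m^4 m^-4)
e10: 0.789798     # exponent on |psi_d| in canopy conductance
psi_d: -2.0       # maximum soil-leaf water potential difference (MPa)
r_tot: 1.0        # total plant-soil hydraulic resistance (MPa m2 s mmol-1)
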