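# Registry of the 28 calibrated quantities: 18 core process parameters,
# 4 auxiliary process parameters, and the 6 initial pool sizes.
#
# Order here fixes the parameter-vector layout used by the kernel, the
# sampler, and every posterior file.  Bounds are the uniform prior ranges
# (scale: log means uniform in log(value)); `default` is the documented
# truth vector of the synthetic site, chosen once to give fluxes and stocks
# of the magnitude observed at a boreal rich fen (annual GPP of a few
# hundred gC m-2, peak LAI near 2.5, SOC near 64 kgC m-2).
registry:
  - {name: f_auto,       low: 0.2,    high: 0.8,    scale: linear, default: 0.48,
     units: "-", description: "fraction of GPP respired autotrophically"}
  - {name: f_fol,        low: 0.01,   high: 0.5,    scale: linear, default: 0.25,
     units: "-", description: "fraction of NPP allocated directly to foliage"}
  - {name: f_lab,        low: 0.01,   high: 0.5,    scale: linear, default: 0.25,
     units: "-", description: "fraction of NPP allocated to the labile pool"}
  - {name: f_root,       low: 0.01,   high: 0.5,    scale: linear, default: 0.20,
     units: "-", description: "fraction of NPP allocated to fine roots (wood takes the residual)"}
  - {name: d_onset,      low: 60.0,   high: 200.0,  scale: linear, default: 140.0,
     units: "day of year", description: "centre of the spring labile-release window"}
  - {name: r_onset,      low: 7.0,    high: 60.0,   scale: linear, default: 21.0,
     units: "days", description: "width (s.d.) of the spring release window"}
  - {name: big_f_onset,  low: 0.1,    high: 0.999,  scale: linear, default: 0.95,
     units: "-", description: "annual completeness of labile release"}
  - {name: d_fall,       low: 200.0,  high: 330.0,  scale: linear, default: 260.0,
     units: "day of year", description: "centre of the autumn leaf-fall window"}
  - {name: r_fall,       low: 7.0,    high: 60.0,   scale: linear, default: 28.0,
     units: "days", description: "width (s.d.) of the leaf-fall window"}
  - {name: big_f_fall,   low: 0.1,    high: 0.999,  scale: linear, default: 0.95,
     units: "-", description: "annual completeness of canopy senescence"}
  - {name: t_root,       low: 1.0e-5, high: 1.0e-2, scale: log,    default: 6.5e-4,
     units: "d-1", description: "fine-root turnover (mortality) rate"}
  - {name: t_wood,       low: 1.0e-6, high: 1.0e-2, scale: log,    default: 5.5e-4,
     units: "d-1", description: "wood / structural turnover rate"}
  - {name: r_lit,        low: 1.0e-4, high: 1.0e-1, scale: log,    default: 4.0e-3,
     units: "d-1", description: "litter mineralisation base rate (to Rh)"}
  - {name: d_lit2som,    low: 1.0e-6, high: 1.0e-2, scale: log,    default: 1.5e-4,
     units: "d-1", description: "litter-to-SOM decomposition base rate"}
  - {name: r_som,        low: 1.0e-8, high: 1.0e-3, scale: log,    default: 3.0e-6,
     units: "d-1", description: "SOM mineralisation base rate"}
  - {name: theta,        low: 0.01,   high: 0.2,    scale: linear, default: 0.08,
     units: "degC-1", description: "exponential temperature sensitivity of SOM mineralisation"}
  - {name: theta_lit,    low: 0.01,   high: 0.2,    scale: linear, default: 0.08,
     units: "degC-1", description: "exponential temperature sensitivity of litter fluxes"}
  - {name: c_eff,        low: 5.0,    high: 100.0,  scale: log,    default: 12.8,
     units: "-", description: "canopy photosynthetic efficiency (foliar N folded in)"}
  - {name: lma,          low: 20.0,   high: 200.0,  scale: log,    default: 60.0,
     units: "gC m-2", description: "leaf mass per area linking foliage C to LAI"}
  - {name: gpp_scale,    low: 0.5,    high: 2.0,    scale: log,    default: 1.0,
     units: "-", description: "whole-canopy scalar on the GPP submodel output"}
  - {name: release_cap,  low: 0.9,    high: 0.9999, scale: linear, default: 0.99,
     units: "-", description: "cap on phenology completeness fractions"}
  - {name: onset_lag,    low: 0.0,    high: 30.0,   scale: linear, default: 7.0,
     units: "days", description: "lag of labile release behind the onset centre"}
  - {name: c_lab0,       low: 1.0,    high: 1000.0, scale: log,    default: 70.0,
     units: "gC m-2", description: "initial labile pool"}
  - {name: c_fol0,       low: 0.1,    high: 100.0,  scale: log,    default: 5.0,
     units: "gC m-2", description: "initial foliage pool (first week of January)"}
  - {name: c_root0,      low: 10.0,   high: 1000.0, scale: log,    default: 247.06,
     units: "gC m-2", description: "initial fine-root pool"}
  - {name: c_wood0,      low: 10.0,   high: 2000.0, scale: log,    default: 282.0,
     units: "gC m-2", description: "initial wood / structural pool"}
  - {name: c_lit0,       low: 1.0,    high: 2000.0, scale: log,    default: 100.0,
     units: "gC m-2", description: "initial litter pool"}
  - {name: c_som0,       low: 5000.0, high: 200000.0, scale: log,  default: 64055.0,
     units: "gC m-2", description: "initial soil organic matter pool"}
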