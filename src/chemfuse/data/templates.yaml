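# Default analyte templates and noise model for the synthetic generator.
#
# TATP's reduced mobility (2.06 cm^2 V^-1 s^-1) is a literature value; the
# remaining peak positions, retention times and IR band positions are
# invented fixtures chosen to be mutually well separated on the instrument
# grids.  The DMMP dimer peak carries a min_concentration gate (50 ppb here;
# the phenomenon is real, the threshold is a stand-in) so it appears only at
# high concentration.  Relative amplitudes are fractions of the detector
# full-scale response at saturation.
analytes:
  acetone:
    ims_peaks:
      - {reduced_mobility: 1.90, relative_amplitude: 1.0, min_concentration: 0.0}
    rt_mean: 45.0     # s
    rt_sd: 0.5        # s (run-to-run retention reproducibility, ~1% RSD)
    ir_bands:
      - {center: 8.15, width: 0.12, relative_amplitude: 1.0}
      - {center: 9.35, width: 0.18, relative_amplitude: 0.45}
  dmmp:
    ims_peaks:
      - {reduced_mobility: 1.78, relative_amplitude: 1.0, min_concentration: 0.0}
      # second (dimer) peak, visible only at high concentration
      - {reduced_mobility: 1.52, relative_amplitude: 0.6, min_concentration: 50.0}
    rt_mean: 60.0
    rt_sd: 0.5
    ir_bands:
      - {center: 9.65, width: 0.15, relative_amplitude: 1.0}
      - {center: 7.95, width: 0.12, relative_amplitude: 0.5}
  tatp:
    ims_peaks:
      - {reduced_mobility: 2.06, relative_amplitude: 1.0, min_concentration: 0.0}
    rt_mean: 80.0
    rt_sd: 0.5
    ir_bands:
      - {center: 8.65, width: 0.15, relative_amplitude: 1.0}
      - {center: 10.25, width: 0.20, relative_amplitude: 0.55}

# baseline_sd and drift_amplitude are fractions of detector full scale;
# rt_jitter_sd is in seconds; amplitude_jitter_sd is the relative sd of the
# per-reading sample-delivery gain (the dominant run-to-run variation of
# repeated vapour measurements); band_ratio_jitter is the uniform half-range
# of the run-to-run relative intensity of secondary IR bands.  White pixel noise sits at the detector
# noise floor (0.05% of full scale).  The default models a stabilized,
# baseline-corrected instrument (drift_amplitude 0); a nonzero
# drift_amplitude adds slow sinusoidal wander to the IMS drift tube for
# robustness studies (the QEPAS channels stay drift-free: lock-in
# photoacoustic detection rejects baseline drift).
noise:
  baseline_sd: 0.0005
  drift_amplitude: 0.0
  rt_jitter_sd: 0.0
  amplitude_jitter_sd: 0.02
  band_ratio_jitter: 0.05

# Training-corpus concentrations (ppb).  2.8 and 5.7 are the two lowest
# levels actually exercised in the bench study; the upper two are stand-ins
# spanning the "higher concentration" regime and are configurable.
concentrations: [2.8, 5.7, 50.0, 500.0]
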