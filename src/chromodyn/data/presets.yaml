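# Preset registry: every number that parameterizes the synthetic generators lives
# here, never hard-coded in operations.  Units are noted per field.
#
# FRAP presets.  k_per_s values follow from the half-times of the experiments
# they emulate (t_half = ln2 / K): TALE-MSR reporter recovery reaches 50% within
# ~30 s in control ESCs and roughly doubles after MSR-transcript depletion; the
# HP1a reporter recovers with t_half ~8 s (control) vs ~13 s (MSR-depleted).
# Mobile fractions: TALE ~75% (an ~25% immobile component), HP1a 85% vs 74%
# (immobile 15% vs 26%).
frap:
  tale_ctrl:
    pre_bleach_frames: 10        # frames before the bleach pulse
    frame_interval_s: 1.0
    n_frames: 310
    bleach_depth: 0.30           # fraction of pre-bleach signal left after the pulse
    mobile_fraction: 0.75
    k_per_s: 0.023105            # ln2 / 30 s
    acq_bleach_per_s: 0.0005     # monoexponential acquisition bleaching, shared by all ROIs
    noise_sd: 0.02               # multiplicative Gaussian, fraction of pre-bleach level
  tale_msr:
    pre_bleach_frames: 10
    frame_interval_s: 1.0
    n_frames: 310
    bleach_depth: 0.30
    mobile_fraction: 0.70
    k_per_s: 0.011552            # ln2 / 60 s (recovery time doubled)
    acq_bleach_per_s: 0.0005
    noise_sd: 0.02
  hp1a_ctrl:
    pre_bleach_frames: 2         # two baseline images one second apart
    frame_interval_s: 1.0
    post_bleach_interval_s: 5.0  # post-bleach frames every 5 s for ~61 s
    n_frames: 15
    bleach_depth: 0.30
    mobile_fraction: 0.85
    k_per_s: 0.086643            # ln2 / 8 s
    acq_bleach_per_s: 0.001
    noise_sd: 0.02
  hp1a_msr:
    pre_bleach_frames: 2
    frame_interval_s: 1.0
    post_bleach_interval_s: 5.0
    n_frames: 15
    bleach_depth: 0.30
    mobile_fraction: 0.74
    k_per_s: 0.053319            # ln2 / 13 s
    acq_bleach_per_s: 0.001
    noise_sd: 0.02

# Chromocenter-dynamics presets for 30-s-interval, 20-min time-lapses.
# fusion/fission rates are per focus per minute and were calibrated once, by
# truth-level simulation, so that the fraction of >=10-min tracks engaging in
# at least one coalescence/cleavage event is ~0.45 (control) and ~0.25
# (MSR-depleted); see docs/methods.md.
dynamics:
  ctrl_dynamics:
    n_foci: 12
    d_app: 1.0e-3            # um^2 / s^alpha
    alpha: 0.8
    velocity: 0.002          # um / s
    fusion_rate: 0.0115      # events per focus per minute  [calibrated]
    fission_rate: 0.0115     # [calibrated]
    frame_interval_s: 30.0
    duration_s: 1200.0
    event_engagement_target: 0.45
  msr_dynamics:
    n_foci: 16
    d_app: 4.0e-4
    alpha: 0.8
    velocity: 0.001
    fusion_rate: 0.0055      # [calibrated]
    fission_rate: 0.0055     # [calibrated]
    frame_interval_s: 30.0
    duration_s: 1200.0
    event_engagement_target: 0.25
  # 1-s-interval preset for MSD / displacement analysis (310 frames)
  displacement_ctrl:
    n_foci: 1
    d_app: 1.0e-3
    alpha: 0.8
    velocity: 0.002
    fusion_rate: 0.0
    fission_rate: 0.0
    frame_interval_s: 1.0
    duration_s: 309.0
    event_engagement_target: 0.0

# Nucleus-rendering presets (2D mid-plane fields of view).
# rna_class_probs are (within, periphery, between): in control ESCs ~17% of
# MSR RNA foci sit within chromocenters, 64% at their periphery and 19%
# between adjacent chromocenters.
nuclei:
  gfp_gapmer:
    image_shape: [192, 192]
    voxel_size_um: 0.1
    nucleus_radius_um: 7.0
    n_chromocenters: {mean: 11, sd: 2, min: 6}
    cc_radius_um: {mean: 0.9, sd: 0.12, min: 0.55}
    cc_intensity: 1200.0
    eu_intensity: 250.0
    background: 40.0
    rna_foci_count: {mean: 5, sd: 1.5, min: 0}
    rna_focus_radius_um: {mean: 0.30, sd: 0.04, min: 0.26}
    rna_intensity: 900.0
    rna_class_probs: [0.17, 0.64, 0.19]
    psf_sigma_um: 0.10
    noise_gaussian_sd: 8.0
  msr_gapmer:
    image_shape: [192, 192]
    voxel_size_um: 0.1
    nucleus_radius_um: 7.0
    n_chromocenters: {mean: 18, sd: 2.5, min: 10}
    cc_radius_um: {mean: 0.62, sd: 0.09, min: 0.40}
    cc_intensity: 1200.0
    eu_intensity: 250.0
    background: 40.0
    rna_foci_count: {mean: 0.5, sd: 0.7, min: 0}
    rna_focus_radius_um: {mean: 0.30, sd: 0.04, min: 0.26}
    rna_intensity: 900.0
    rna_class_probs: [0.17, 0.64, 0.19]
    psf_sigma_um: 0.10
    noise_gaussian_sd: 8.0
  rnase:
    image_shape: [192, 192]
    voxel_size_um: 0.1
    nucleus_radius_um: 7.0
    n_chromocenters: {mean: 11, sd: 2, min: 6}
    cc_radius_um: {mean: 0.9, sd: 0.12, min: 0.55}
    cc_intensity: 1200.0
    eu_intensity: 250.0
    background: 40.0
    rna_foci_count: {mean: 0.0, sd: 0.0, min: 0}
    rna_focus_radius_um: {mean: 0.30, sd: 0.04, min: 0.26}
    rna_intensity: 900.0
    rna_class_probs: [0.17, 0.64, 0.19]
    psf_sigma_um: 0.10
    noise_gaussian_sd: 8.0

# Droplet-plate presets.  protein_concs_uM are the 2x labels of the dilution
# series (two-fold from 200 uM down to 1.6 uM, plus 0); critical_conc_uM is
# the minimum concentration on that series at which a species forms droplets.
# Forward-strand species yield larger droplets than reverse-strand species of
# the same repeat number.
plates:
  msr_panel:
    protein_concs_uM: [200.0, 100.0, 50.0, 25.0, 12.5, 6.25, 3.125, 1.6, 0.0]
    rna_species:
      - {name: msr_1rep_fwd, critical_conc_uM: 50.0, droplet_size_scale_um: 5.0}
      - {name: msr_1rep_rev, critical_conc_uM: 50.0, droplet_size_scale_um: 3.4}
      - {name: msr_4rep_fwd, critical_conc_uM: 12.5, droplet_size_scale_um: 6.0}
      - {name: msr_4rep_rev, critical_conc_uM: 12.5, droplet_size_scale_um: 4.1}
      - {name: polyU, critical_conc_uM: 12.5, droplet_size_scale_um: 4.5}
      - {name: no_rna, critical_conc_uM: .inf, droplet_size_scale_um: 0.0}
    field_shape_px: [256, 256]
    pixel_size_um: 0.5
    droplet_count_mean: 25
    background: 100.0
    droplet_intensity: 900.0
    noise_gaussian_sd: 10.0

# FLIM presets: SiR-DNA lifetimes (ns); heterochromatin is more compact and
# shows the shorter lifetime.  Control vs MSR-depleted lifetimes drop, more so
# in heterochromatin.
flim:
  gfp_gapmer:
    tau_het_ns: 2.60
    tau_eu_ns: 2.90
    photons_per_region: 100000
    rep_period_ns: 25.0
    n_bins: 256
  msr_gapmer:
    tau_het_ns: 2.40
    tau_eu_ns: 2.82
    photons_per_region: 100000
    rep_period_ns: 25.0
    n_bins: 256
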