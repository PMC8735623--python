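# Bundled parameter presets for the macrophage germband-invasion
# quantification pipeline.  Every numeric entry carries a provenance
# comment naming the figure panel / legend / results paragraph of the
# study it was transcribed from, or "synthetic" where the study prints
# no absolute value.
#
# Units: speeds in um/min, lengths/widths in um, persistence and
# mem/cyto ratios dimensionless, intensities in batch-normalized units.

tracks:
  control_pre_gb:
    speed_um_min: 3.61      # Fig 2C legend: control pre-gb speed
    persistence: 0.56       # S2 Fig A legend: control pre-gb persistence
  DfosDN_pre_gb:
    speed_um_min: 3.00      # Fig 2C legend: DfosDN pre-gb speed
    persistence: 0.58       # S2 Fig A legend: DfosDN pre-gb persistence
  control_gb_entry:
    speed_um_min: 1.98      # Fig 2E legend: control gb-entry speed
  DfosDN_gb_entry:
    speed_um_min: 1.53      # Fig 2E legend: DfosDN gb-entry speed
  control_vnc:
    speed_um_min: 4.55      # Fig 2F legend: control vnc speed
    persistence: 0.61       # S2 Fig A legend: control vnc persistence
  DfosDN_vnc:
    speed_um_min: 4.93      # Fig 2F legend: DfosDN vnc speed
    persistence: 0.54       # S2 Fig A legend: DfosDN vnc persistence

linescan:
  # Membrane-to-cytoplasm ratios printed in the Results paragraph on
  # cortical Rho1/Dia activity and the Fig 4N/P legends.
  Dia:
    control:    {ratio: 2.46}  # Results: mem/cyto = 2.46 in control
    Rho1DN:     {ratio: 1.76}  # Results: 1.76 for Rho1DN
    DfosDN:     {ratio: 1.9}   # Results: 1.9
    cher_RNAi:  {ratio: 1.88}  # Results: 1.88
    TM4SF_RNAi: {ratio: 1.97}  # Results: 1.97
  DiaRBD:
    control:    {ratio: 1.15}  # Results: mem/cyto = 1.15 in control
    Rho1DN:     {ratio: 0.76}  # Results: 0.76 for Rho1DN
    DfosDN:     {ratio: 0.91}  # Results: 0.91
    cher_RNAi:  {ratio: 0.83}  # Results: 0.83
    TM4SF_RNAi: {ratio: 0.92}  # Results: 0.92

intensity:
  moe:
    # Per-embryo Moe::3xmCherry means, batch-normalized to control.
    control: {mean: 1.0, sd: 0.2}   # Fig 4D: normalization target 1; SD 0.2
    DfosDN:  {mean: 0.47, sd: 0.4}  # Fig 4D: 53% reduction; SD 0.4

shape:
  gb:
    # Length/width SDs from S5 Fig C legend.  Absolute means are not
    # printed in the study; the means below are synthetic choices for a
    # first entering macrophage (aspect ratio ~2) scaled so that the
    # DfosDN group is 23% longer and 12% thinner than control
    # (S5 Fig C / Results).
    control: {len_mean: 20.0, len_sd: 3.4, wid_mean: 10.0, wid_sd: 1.3}
    DfosDN:  {len_mean: 24.6, len_sd: 5.7, wid_mean: 8.8, wid_sd: 1.0}
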