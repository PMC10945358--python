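# Natural-peatland scenario: three planted co-occurrence modules; CMR and
# carbohydrates share module 0, planting a carbohydrate-CMR Pearson
# correlation of 0.60 (phenolics are unlinked noise, i.e. no planted
# phenolics-CMR association in the natural condition).
name: natural
land_use: natural
n_taxa: 100
sequencing_depth: 2000
archaea_fraction: 0.05
noise_sd: 1.0
modules:
  - {size: 15, within_correlation: 0.85}
  - {size: 15, within_correlation: 0.85}
  - {size: 12, within_correlation: 0.80}
cmr_module: 0
cmr_module_r: 0.7746       # anchor: CMR vs module-0 signal (sqrt of 0.60)
trait_cmr_r:
  carbohydrates: 0.60
# Location/scale decoration per trait (units: CMR mg C kg-1 SOC d-1; SOC g
# kg-1; phenolics mg g-1; carbohydrates % of DOC; DOC mg kg-1; nutrients mg
# kg-1 except TN/TP g kg-1). Affine only - correlations are unaffected.
trait_scales:
  CMR: [6.0, 2.0]
  phenolics: [2.5, 0.6]
  carbohydrates: [30.0, 8.0]
  DOC: [450.0, 100.0]
  FTIR_1630_1030: [1.1, 0.2]
  SOC: [420.0, 60.0]
  TN: [18.0, 3.0]
  TP: [1.2, 0.3]
  AN: [350.0, 80.0]
  AP: [15.0, 5.0]
  pH: [5.2, 0.4]
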