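# Cultivated-peatland scenario: both DOC fractions are negatively coupled
# to mineralization through module 0 - planted phenolics-CMR correlation
# -0.58 and carbohydrate-CMR correlation -0.66. With independent trait
# noises the implied phenolics-carbohydrate correlation is the product of
# the two module links (about +0.53).
name: cultivated
land_use: cultivated
n_taxa: 100
sequencing_depth: 2000
archaea_fraction: 0.05
noise_sd: 1.0
modules:
  - {size: 15, within_correlation: 0.85}
  - {size: 15, within_correlation: 0.85}
  - {size: 12, within_correlation: 0.80}
cmr_module: 0
cmr_module_r: 0.85         # anchor: CMR vs module-0 signal
trait_cmr_r:
  phenolics: -0.58
  carbohydrates: -0.66
trait_scales:
  CMR: [12.0, 3.0]
  phenolics: [1.2, 0.4]
  carbohydrates: [12.0, 4.0]
  DOC: [300.0, 70.0]
  FTIR_1630_1030: [0.8, 0.15]
  SOC: [300.0, 50.0]
  TN: [12.0, 2.0]
  TP: [1.8, 0.4]
  AN: [250.0, 60.0]
  AP: [30.0, 8.0]
  pH: [6.0, 0.4]
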