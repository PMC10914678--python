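# Shared run configuration for the analysis scripts: plasma SERPINA1
# (M1V/M3 backbones), three N-glycosylation sites, glycoform heterogeneity at
# Asn271, triple exoglycosidase digestion applied so that core- and
# antennary-fucosylated isomers become mass-distinguishable, and a binding
# model in which core fucose stabilizes (x1.8 odds) and antennary fucose
# destabilizes (x0.6 odds) the SERPIN-protease complex.
sequence: SERPINA1
variants: [M1V, M3]
glycosites: [70, 107, 271]
varied_site: 271
glycoforms:
  - {name: A2G2S2, antennae: 2, sialylated: true}
  - {name: A2G2S2Fc, antennae: 2, sialylated: true, core_fucose: true}
  - {name: A2G2S2Fa, antennae: 2, sialylated: true, antennary_fucoses: 1}
enzyme_panel:
  enzymes: [neuraminidase, b14_galactosidase, glcnacase]
  mode: intact_glycoprotein
  apply: true
binding:
  base_bound_fraction: 0.5
  factor_core_fucose: 1.8
  factor_antennary_fucose: 0.6
  factor_branch: 1.0
  protease_mass: 25900.0
  protease_name: elastase
simulation:
  charge_center: 14.0
  charge_spread: 1.0
  resolution: 25000.0
  intensity_cv: 0.1
  replicates: 3
policies:
  normalization: global
  ambiguity: drop
seed: 1
outdir: results
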