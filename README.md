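# serpinms

Native mass spectrometry (MS) of intact plasma glycoproteins can resolve
individual **proteoforms** — one genetic backbone (e.g. the common SERPINA1
variants M1V, M1A, M2, M3) combined with one exact set of modifications
(N-glycoforms, cysteinylation, N-terminal truncation) — and, critically, can
do so on **protein–protease complexes**, linking each proteoform to its
binding behaviour. `serpinms` is a Python toolkit for that analysis style,
aimed at native-MS and glycoproteomics practitioners:

* **Proteoform mass libraries** — combinatorial enumeration of variant ×
  truncation × cysteinylation × per-site glycoform, with average and
  monoisotopic masses, collision reports for near-isobaric traps
  (M2 vs M1A at 5.02 Da; +2 Fuc vs +1 Neu5Ac at 1.03 Da), and
  SERPIN–protease complex masses.
* **Glycan topology + exoglycosidase simulation** — N-glycans as rooted
  trees; rule-based digestion (neuraminidase, β1-4 galactosidase,
  GlcNAcase, α1-6 fucosidase) with the steric block that makes
  core-fucosylated vs antennary-fucosylated **linkage isomers** —
  identical intact mass — separable by 162 Da (double panel) or 365.3 Da
  (triple panel).
* **Spectrum simulation** — multi-charge native spectra of apo + complex
  ensembles under a glycan-feature-modulated binding model, with replicate
  noise and adduct series; the synthetic ground truth for validating the
  inference chain.
* **Deconvolution & assignment** — peak picking, charge inference from the
  envelope, tolerance matching with explicit ambiguity groups.
* **Quantification & statistics** — complex:apo abundance ratios per
  glycoform class with replicate mean ± SD, Student's t comparisons, and
  stoichiometric trend tests (ratio vs number of fucoses / branch units).

The binding model at the core: a proteoform carrying `c` core fucoses, `a`
antennary fucoses and `b` extra Gal-GlcNAc branch units binds its protease
with odds

```
odds(c, a, b) = p0/(1−p0) · f_c^c · f_a^a · f_b^b
```

so its expected complex:apo abundance ratio equals those odds, and
per-residue effects appear as geometric trends of ratio against feature
count. Factors above 1 stabilize the complex (core fucosylation,
branching); below 1 destabilize it (antennary fucosylation).

## Worked example

Digest the fucose linkage isomers and see the mass separation appear:

```python
from serpinms.glycan_model import biantennary
from serpinms.enzyme_engine import DOUBLE_PANEL, TRIPLE_PANEL, isomer_discrimination

core = biantennary(sialylated=True, core_fucose=True)       # Fuc α1-6 on root GlcNAc
ant  = biantennary(sialylated=True, antennary_fucoses=1)    # Fuc α1-3 on an antenna
print(core.composition() == ant.composition())              # True — isomers
print(f"{isomer_discrimination(core, ant, DOUBLE_PANEL).mass_difference:.2f}")
print(f"{isomer_discrimination(core, ant, TRIPLE_PANEL).mass_difference:.2f}")
```

```
True
162.14
365.34
```

162.14 Da is one galactose: the antennary fucose sterically blocks the
β1-4 galactosidase on its own antenna, so that product keeps a Gal the
core-fucosylated product loses. The triple panel adds the GlcNAcase and the
gap grows to Gal + GlcNAc.

The numbered scripts under `analysis/` run the full study on synthetic
data (library → digestion → simulated replicate spectra → assignment →
ratios and trends). For example:

```bash
python analysis/04_assign_quantify.py
```

```
complex:apo ratio by core fucoses:
  core_fucose count 0: 0.809 +/- 0.012 (n=3)
  core_fucose count 1: 1.791 +/- 0.083 (n=3)

complex:apo ratio by antennary fucoses:
  antennary_fucose count 0: 1.372 +/- 0.025 (n=3)
  antennary_fucose count 1: 0.612 +/- 0.021 (n=3)

core-fucosylated vs non-fucosylated ratio: 1.791 vs 0.809, t = 20.20, p = 0.0000
```

Three simulated replicates were generated with core fucose stabilizing the
SERPINA1–elastase complex (odds ×1.8) and antennary fucose destabilizing it
(×0.6); the recovered stratified ratios reproduce those factors from the
spectra alone. `analysis/05_trends_stats.py` extends this to stoichiometric
trends (×0.6 per antennary fucose over 0–3; ×1.3 per branch unit over 0–4;
direction recovered in 100/100 seeds, fold within 1%) and calibrates the
ratio t test under the null (42/1000 rejections at α = 0.05).

The same stages are scriptable via the CLI against a YAML config
(`analysis/config.yaml` is a complete example):

```bash
serpinms build-library analysis/config.yaml
serpinms simulate analysis/config.yaml
serpinms quantify analysis/config.yaml   # -> results/report.json
```

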