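# Methods

`serpinms` models what a native mass spectrometry experiment on plasma
serine protease inhibitors (SERPINs) measures: intact masses of proteoforms
— one genetic backbone plus one exact set of modifications — and of their
noncovalent/covalent complexes with serine proteases, and how the relative
abundance of the complex depends on glycan features. This note records the
models, conventions, defaults and their rationale.

## Mass conventions

All intact-level arithmetic uses **average residue masses** (the classical
ExPASy/GlycoMod tables, stored to 4 decimal places), because envelope-level
native MS of 50–80 kDa glycoproteins measures average, not monoisotopic,
masses. Monoisotopic values (amino acids via `pyteomics`, monosaccharides
from elemental compositions) are available for glycopeptide-scale work.

Monosaccharide residue (dehydrated) masses, Da average:
Hex 162.1424, HexNAc 203.1950, Fuc 146.1430, Neu5Ac 291.2579. Useful
identities that follow: two fucoses = 292.29 Da vs one Neu5Ac = 291.26 Da
(a 1.03 Da near-collision at intact level), and the sialylated branch unit
Neu5Ac-Gal-GlcNAc = 656.60 Da, the spacing of the branching peak series.

A protein chain weighs the sum of its residues plus one water (18.0153 Da
average). The empty chain is accepted and weighs one water — convenient for
fragment arithmetic. Cysteinylation (free-cysteine disulfide adduct,
C3H5NO2S) adds 119.1442 Da average. The electrospray relation uses a proton
mass of 1.00728 Da.

**Numbering vs mass.** Residue positions are quoted in precursor numbering
(signal peptide included), which is how the glycosites (Asn70, Asn107,
Asn271), the cysteinylation site (Cys256) and the variant positions
(125/237/400) are conventionally labelled for SERPINA1. Masses, however, are
computed on the **mature chain** (Glu25–Lys418 for SERPINA1): that is the
species in plasma, and it is what puts the tri-glycosylated proteoforms in
the observed 51–53 kDa window. The N-terminal truncation removes precursor
residues 25–29; the canonical P01009 sequence has Glu at position 25
(mature chain starts EDPQG), although the truncated stretch is sometimes
labelled starting "Asp25" in the literature.

## Glycan topology and exoglycosidase rules

Glycans are rooted trees of residues (Man/Gal/GlcNAc/Fuc/Neu5Ac) with
parent linkages (e.g. `b1-4`, `a1-6`, `a2-6`) and a core flag marking the
Man3GlcNAc2 pentasaccharide. Hexose isomers (Man/Gal) and HexNAc variants
weigh the same; identity matters only to the enzyme rules. Core fucose is
α1-6 on the reducing-end GlcNAc; antennary fucose is α1-3/4 on an antenna
GlcNAc. Antennae are sorted by elaboration state when a glycan is built, so
topologies differing only in antenna placement — experimentally
indistinguishable at the intact level — compare equal.

Digestion is all-or-none: each enzyme removes matching terminal (leaf)
residues iterated to a fixpoint, the idealization of an overnight bench
digest (no partial-digestion kinetics). The rules:

| enzyme | removes | blocked by |
|---|---|---|
| neuraminidase | terminal Neu5Ac, any α2-x linkage | nothing (fucose-insensitive) |
| β1-4 galactosidase | terminal β1-4 Gal | α1-3/4 fucose on the Gal's own GlcNAc |
| GlcNAcase | terminal β-linked antenna GlcNAc | nothing extra (a fucosylated GlcNAc is not terminal) |
| α1-6 fucosidase | terminal α1-6 fucose | inactive in intact-glycoprotein mode |

GlcNAcase acts on β1-2/3/4/6 antenna GlcNAc — broad β-N-acetyl-
glucosaminidase specificity — so all non-fucosylated antennae are removed on
tri/tetra-antennary substrates too. α1-6 fucosidase has an explicit
substrate mode (`intact_glycoprotein`, the default, vs `free_glycan`):
on folded glycoproteins the core fucose is shielded by the glycan chain and
nothing comes off.

Panels run sequentially, each enzyme to fixpoint, then loop to a global
fixpoint; for these rule sets the result equals the simultaneous fixpoint
regardless of order (property-tested).

The two consequences that carry the analysis:

* **Double panel** (neuraminidase + galactosidase) maps a core-fucosylated
  and a mono-antennary-fucosylated bi-antennary glycan — compositional
  isomers, identical intact mass — to products differing by exactly one
  galactose, **162 Da**.
* **Triple panel** (+ GlcNAcase) trims any complex-type glycan to
  Man3GlcNAc2, plus its core fucoses, plus one Galβ1-4(Fucα1-3/4)GlcNAc
  trisaccharide per antennary fucose. The isomer gap grows to Gal + GlcNAc
  = **365.34 Da** average (365.13 monoisotopic). A rounded value of 366 Da
  is sometimes quoted; the computed residue sum is 365.33–365.34 and that
  is what this package reports.

Antennary fucose is modelled on galactosylated antennae (Lewis-type
epitopes); a fucose on a bare GlcNAc antenna would leave a GlcNAc-Fuc
disaccharide instead of the trisaccharide and is outside the composition
law above.

## Proteoform and complex model

A proteoform = backbone variant × truncation state × cysteinylation count ×
one glycan per site. SERPINA1 presets: variants M1V (canonical), M1A
(V237A), M3 (E400D), M2 (R125H+E400D), plus the deficiency alleles S
(E288V) and Z (E366K); N-terminal truncation des25–29; glycosites
(70, 107, 271). Two glycosite presets are kept for SERPINA3 — the
Asn133-containing and the Asn33-containing six-site lists — because both
circulate; the package does not arbitrate.

Library enumeration is the full cartesian product, deduplicated by per-site
glycan **composition** by default (isomers are one intact-level mass class)
or by **topology** (`dedup="topology"`) when isomer-specific behaviour must
be simulated. A collision report lists near-isobaric pairs; at ~51 kDa the
canonical traps are M2 vs M1A (5.02 Da) and +2 Fuc vs +1 Neu5Ac (1.03 Da).

Complex masses default to `intact_sum` (SERPIN + protease; atoms are
conserved through acyl-enzyme formation). `loop_fragment_released`
additionally subtracts the C-terminal reactive-center-loop fragment
(cleavage position → C terminus, as a peptide with water) for the case
where the cleaved tail dissociates; whether it does in a given experiment
is not generally known, hence the conservative default.

## Binding model

Each proteoform binds the protease with odds

```
odds(c, a, b) = p0/(1-p0) · f_c^c · f_a^a · f_b^b
```

where `c`, `a`, `b` are its core-fucose, antennary-fucose and extra-branch
counts (branches beyond bi-antennary, summed over sites), `p0` is the bound
fraction of a feature-free proteoform, and the `f` factors are per-residue
odds multipliers (>1 stabilizes). The expected complex:apo abundance ratio
of a class equals its odds, so multiplicative per-residue effects appear as
geometric (log-linear) ratio trends against feature count — the
stoichiometric signature the trend test looks for.

## Spectrum simulation

Peaks are envelope-level Gaussians (no isotope structure): one peak per
(species, charge, adduct) at `(M + z·1.00728)/z`, FWHM = (m/z)/R, apex
height = abundance × charge-envelope weight. The charge envelope is a
Gaussian over integer z (center `charge_center`, width `charge_spread`,
weights normalized per species); if `reference_mass` is set the center
scales with sqrt(mass/reference), the native-MS trend that places an
~80 kDa complex at higher z (m/z > 4500) than 51 kDa apo protein.

Noise has two parts: per-peak multiplicative log-normal height jitter with
a configured CV (mean-one parametrization, so expected heights stay
nominal) — this is what drives replicate-to-replicate ratio scatter — and
an optional additive uniform baseline. An optional GlcNAc adduct series
adds satellites at +203.195 Da (neutral) with geometric height decay, off
by default; it reproduces the interference that motivates the triple panel
over the double one. All randomness flows from one master seed; replicate
seeds are spawned from it, so runs are bit-reproducible.

Default grid step is FWHM/6 (a warning fires above FWHM/3). With zero
noise the numerically integrated spectrum equals the analytic sum of peak
areas to 0.1%, and heights are proportional to abundances.

`simulate_ratio_replicates` is the reduced generator used for the
statistical calibration studies: it applies the same mean-one log-normal
noise directly to the apo/complex abundances of each class, skipping the
render-and-repick round trip. A spectrum-level test verifies the full chain
(simulate → pick → infer → assign → quantify) reproduces the binding odds,
which justifies running the 100-seed trend study and the 1,000-experiment
t-test calibration at the abundance level; at the study design size
(3 replicates, ~10 glycoform classes, CV 0.1) both finish in seconds.

## Deconvolution and assignment

Baseline and noise are estimated from the lowest-intensity quartile of the
profile (median, and 1.4826×MAD). Local maxima above
baseline + `min_snr`×noise are centroided by log-parabolic interpolation
over the three points around the apex — exact for a Gaussian — with an
intensity-weighted FWHM-window mean as fallback; peak area integrates that
window.

Charge inference generalizes the adjacent-charge relation
z = round((m2 − mp)/(m1 − m2)) to the whole envelope by mass coincidence:
for each peak and candidate z, count how many other peaks have some charge
whose implied neutral mass agrees within `mass_tol` (default 2 Da). The
best-supported z wins; no support, or a tie, flags the peak (z = 0) rather
than guessing. Overlapping envelopes of co-eluting proteins are only ever
flagged, not resolved — matrix deconvolution is out of scope.

Assignment matches implied neutral masses against the library within a
tolerance (default 1.0 Da at intact level — native envelope accuracy; use
~10 ppm for digested/glycopeptide masses). Every candidate within tolerance
is reported, sorted by |error| then label so library order is irrelevant.
Peaks with more than one candidate carry an ambiguity-group id shared by
peaks with the same candidate set; downstream quantification either drops
ambiguous peaks (default) or splits their intensity equally. Ambiguity is
deliberately a first-class output: the 1.03 Da and 5.02 Da collisions above
are only resolvable by orthogonal evidence, and silently picking one
candidate would manufacture certainty.

## Quantification and statistics

Intensity per proteoform class is the apex-height sum over its charge
states (area optional). Relative abundances normalize within condition
(apo, complex) by default, or globally. Per-condition normalization
rescales every complex:apo ratio by the constant (total apo)/(total
complex) factor — harmless for fold changes, trends and group comparisons,
but absolute ratios equal the binding odds only under global normalization.

Ratios are computed per replicate (ratio of abundances, not abundance of
ratios), then summarized as mean ± SD (n−1) — the bar-graph convention.
Replicates with zero apo abundance are flagged and excluded, not
propagated.

Group comparison uses a two-sided two-sample t test. The **pooled
(classical Student's) variant is the default**: at the triplicate scale of
these experiments the Welch–Satterthwaite degrees of freedom are poorly
estimated and Welch's test is markedly conservative (measured type-I error
~0.03 at nominal 0.05 under the simulated null, vs ~0.046 for pooled), and
the pooled test is also the test the source experiments report. Welch
remains available (`variant="welch"`). Degenerate zero-variance input is
guarded: identical constant groups return (t=0, p=1), separated constant
groups (t=±inf, p=0).

Feature trends need ≥3 distinct counts. Direction follows the sign of the
Spearman rank correlation of mean ratio vs count (flat for constant means);
the per-step fold change is exp(slope) of the least-squares fit of
log(mean ratio) on count, exact for geometric series and the natural
estimator under the multiplicative binding model.

Site-specific fucosylation summaries consume glycopeptide tables through a
minimal column contract (site, placement ∈ {core, antennary, none},
intensity) with a rename map, so real glycopeptide-search exports adapt
with thin configuration; percentages are intensity shares per site and sum
to 100.

## What the synthetic data does and does not emulate

Emulated: multi-charge native envelopes of 50–80 kDa species; glycoform
fine structure (branch ladders, ±fucose, ±cysteinylation, near-isobaric SNP
backbones); apo and complex populations under the multiplicative binding
model; replicate log-normal intensity scatter; optional GlcNAc adduct
satellites and uniform baseline.

Not emulated: isotopic fine structure; asymmetric/Lorentzian peak shapes
and detector physics; the dominant albumin/transferrin background of whole
plasma (only a flat baseline); partial digestion; chromatographic or
ion-mobility dimensions. Passing tests therefore demonstrate correctness of
the inference chain under the stated noise model, not robustness to every
real-spectrum pathology — in particular, heavily overlapped envelopes must
be resolved upstream or the affected peaks will be flagged/dropped.

## Problem sizes and numerical choices

Simulation studies run at the experimental design size: 3 replicates,
CV 0.1, ~10 glycoform classes; 100 seeds for trend recovery, 1,000
simulated 3-vs-3 experiments for t-test calibration; round-trip closure
uses a 12-proteoform library at R = 25,000 over z ≈ 12–15, noiseless, with
0.1 Da recovery. Tolerances and tie-breaks: assignment 1.0 Da (intact),
charge coincidence 2.0 Da, min SNR 3; ambiguous charges and assignments are
flagged, never guessed; grid FWHM/6.

## Known limitations

* Enzyme rules are qualitative (block/allow); no kinetics, no partial
  products, no endoglycosidases.
* The binding model is multiplicative and site-agnostic: feature counts are
  summed over glycosites, although the biology localizes the effect to the
  RCL-proximal site (Asn271 in SERPINA1/A3). Site-resolved binding factors
  would need site-resolved intact evidence the intact level cannot give.
* Charge inference assumes at least two charge states per species (or a
  user-fixed z).
* O-glycans, hybrid/high-mannose biosynthesis and 3D conformers are out of
  scope; SERPINA3 is supported through its site presets and the generic
  machinery, with no bundled sequence fixture.
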