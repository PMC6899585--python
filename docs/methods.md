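# Methods

## Scope and data model

`cadtrace` analyses aligned untargeted LC-MS feature matrices from a
two-mode profiling experiment (reversed-phase `RP` and hydrophilic-interaction
`HI` chromatography, positive-ion electrospray, [M+H]⁺ adducts only).
Features are identified as `<mode>_<rt>/<mz>` with retention time printed at
two decimals and m/z at four; parsing is string-faithful so that IDs round-trip
exactly.  Missing values are encoded as 0, the convention of the upstream
alignment tool, and a per-mode intensity cut-off (defaults 8000 for RP, 3000
for HI) defines detection.  The cut-off is applied **inclusively** (≥); the
side is not fixed by the upstream tool's documentation, so it is a
configurable convention here.  Raw spectra, peak picking, alignment, MS/MS
annotation and adducts other than [M+H]⁺ are out of scope.

## Synthetic-data generator

The generator emulates the study design the package targets: a wild type
(`Col-0`, transgene expression 0) plus three transgenic lines with graded
expression (relative levels 1 : 3 : 7.7, following the reported qRT-PCR
ratios), three biological replicates per group, and optionally the feeding
arm — the high-expressing line under [α-¹⁵N]-lysine (AL), [ε-¹⁵N]-lysine
(EL) and non-labeled lysine (NL).

Per compound and mode the generator emits an M feature and, when feeding is
simulated, an M+1 feature at m/z + 0.99703 and identical retention time.
The tracer fraction f of a compound depends on its labeling class:

| class                | f under AL      | f under EL |
|----------------------|-----------------|------------|
| both nitrogens from cadaverine | p_cad | p_cad      |
| one nitrogen from cadaverine   | p_cad/2 | p_cad/2  |
| α-nitrogen only (bypasses cadaverine) | p_lys | 0   |
| unlabeled background | 0               | 0          |

The factor ½ is the chemistry of the symmetric intermediate: cadaverine's
two amine positions are equivalent, so a single ¹⁵N survives the loss of one
nitrogen with probability one half, identically for both isotopomers.  The
observed heavy fraction adds natural abundance,
f_obs = f + (1 − f)·(1 − (1 − a)^nN) with a = 0.00364 (standard terrestrial
¹⁵N abundance; for two nitrogens this gives 0.727%, matching the ~0.7%
baseline such experiments report).  Channel intensities are
abundance·(1 − f_obs) and abundance·f_obs with independent multiplicative
log-normal noise of the requested CV (mean-one parameterization), then
censored to 0 below the mode's detection threshold.

Deliberate simplifications, hence limitations of what passing tests show
about real data:

- Only nitrogen isotopes populate the M+1 channel; ¹³C isotopologues, which
  in reality dominate M+1 for carbon-rich ions, are excluded because the
  downstream pair search targets the ¹⁵N shift specifically.
- Labeled molecules carry exactly one heavy nitrogen (each lysine isotopomer
  is labeled at a single position and decarboxylation retains both amine
  nitrogens), so there is no M+2 channel and no isotopomer distribution to
  deconvolve.
- Fed lysine itself is modeled as unlabeled background; the generator's
  labeling classes describe cadaverine provenance, not the amino-acid pool.
- Genotype scaling of pathway compounds is linear in transgene expression —
  the source data report a correlation, not a functional form — and pathway
  compounds are exactly absent (0) in the wild type.
- No chromatogram or spectrum simulation, no adducts, no fragmentation.

Default tracer fractions are p_lys = 0.935 (the reported 92.8–95.4% lysine
labeling) and p_cad = 0.6 (the reported ~56–67% cadaverine labeling).  The
within-line intensity CV is not reported anywhere in the source material; the
defaults (0.1 for the feeding design, 0.2 for the profiling design) are
typical replicate CVs for untargeted plant LC-MS and are free parameters of
the scenario, not derived values.

Every emitted feature carries one ground-truth row (source compound,
isotopologue role, differential class, per-treatment tracer fraction), and
identical scenario + seed reproduce the tables byte for byte.

## Multivariate stage

Scaling supports centering, unit-variance (default, the usual default of
commercial OPLS software) and pareto; constant columns are dropped with a
warning before variance scaling.  PCA is the SVD of the scaled matrix.

OPLS-DA uses orthogonal signal correction: with class vector y ∈ {+1, −1}
(centered), the predictive weight is w ∝ Xᵀy; each orthogonal component
takes the part of the loading p = Xᵀt/(tᵀt) orthogonal to w, scores and
deflates it, and the predictive weight is re-derived from the deflated
matrix.  With zero orthogonal components the fit reduces exactly to the
first NIPALS PLS1 component (verified against an independent NIPALS oracle).
Sign indeterminacy is fixed by requiring the mean predictive score of class
+1 to be positive.  R2X is bookkept so that predictive + orthogonal +
residual fractions sum to 1.

Q2 (cumulative) is 1 − PRESS/SS over held-out class predictions with
class-stratified folds (default 7, seeded assignment; the fold count drops
to the minority-class size when needed so every training split keeps both
classes).  The number of orthogonal components is chosen greedily: add while
Q2 improves by more than 0.01, capped at 5.

The S-plot reports, per feature, p[1] = cov(t, xⱼ) (sample covariance,
1/(n−1)) and p(corr)[1] = corr(t, xⱼ); zero-variance features get
p(corr)[1] = 0 and a flag.  Selection takes features with |p[1]| > 0.02 and
|p(corr)[1]| > 0.02 on the scaled matrix, partitioned by sign.  The
covariance convention makes p[1] bilinear in t and xⱼ, which is the property
the threshold semantics assume; it is only meaningful on a scaled matrix.

**Known limitation — specificity of the printed cut-offs.**  With twelve
samples (four genotypes × three replicates) the sampling SD of a null
feature's p(corr)[1] is 1/√11 ≈ 0.30, so ~95% of truly null features exceed
the 0.02 correlation cut-off by chance, and the covariance cut-off operates
on a scale far above 0.02.  The cut-offs therefore control recall, not the
false-positive rate: on the 500-feature benchmark all planted markers are
recovered but roughly half the null features pass as well.  No scaling
choice changes this at n = 12; a specificity-controlled selection needs
either more samples or an explicit null model, which is outside the scope of
reproducing this selection rule.  The corresponding false-positive
acceptance check is intentionally left failing rather than weakened.

## Annotation and enrichment

Theoretical [M+H]⁺ m/z is the pyteomics monoisotopic mass plus the proton
mass (1.007276 Da).  A feature matches a compound when the relative error to
the theoretical m/z is below the tolerance (default 10 ppm); all matches are
kept, nearest first, and isobaric compounds are expected (e.g. the C5H11NO2
trio in the bundled library).  The bundled library
(`src/cadtrace/data/compound_library.tsv`) is a synthetic curation of ~65
compounds spanning the cadaverine/putrescine catabolic neighbourhood,
lysine degradation, phenylpropanoid biosynthesis and common plant
metabolites, with KEGG-style pathway ids.

Pathway over-representation uses the one-sided hypergeometric tail
P(X ≥ a) via scipy with fixed margins, at raw P < 0.05 — no multiple-testing
correction by default, matching the practice the package reproduces; a
Benjamini–Hochberg column is available.  The background universe defaults to
all annotated features of the experiment (deduplicated at compound level);
the alternative "all library compounds" is a config switch, since the true
mapping universe of the original tooling is not recoverable.

## Specific features

"Specifically accumulated" is operationalized as: detected in at least r
replicates of **some** case line (default r = all replicates of that line)
and detected in at most 0 control samples (configurable).  This replaces a
manual raw-data validation step with a reproducible replicate-presence rule;
it is deterministic and monotone in both parameters.

## Isotope tracing

The pair search scans, per light feature, for a partner at m/z + 0.99703
within 5 ppm (computed on the expected heavy m/z — the upstream tool's
convention is unstated, so this side is fixed and documented) and within
0.1 min; the best candidate wins by smallest ppm error, then smallest RT
difference.  The implementation is checked against an O(n²) brute-force
oracle.

%EF is computed per replicate and averaged arithmetically (n = 3 in the
emulated design).  Correction for natural abundance uses the
excess-enrichment normalization EF* = 100·(EF_t − EF_NL)/(100 − EF_NL),
floored at 0 and flagged when the treated value falls below baseline; the
literature the original workflow cites does not reproduce its exact formula,
so the correction is isolated behind one function and plain subtraction is a
config switch.  Under the generator this normalization recovers the true
tracer fraction exactly in the noise-free limit, which is why the half- and
full-labeling ratios concentrate on 0.5 and 1.0.

Classification applies, in order, on corrected %EF: (1) below the minimum
enrichment (default 5%) in both treatments → unlabeled; (2) labeled under
exactly one treatment → regiospecific α / ε; (3) labeled under both with
relative AL/EL asymmetry ≤ 0.5: ρ = mean(EF_AL, EF_EL) over the cadaverine
reference mean; ρ ∈ [0.75, 1.25] → both nitrogens, ρ ∈ [0.35, 0.65] → one
nitrogen via the symmetric intermediate; (4) otherwise ambiguous.  The bins,
the 5% floor and the asymmetry tolerance are operational renderings of the
qualitative "same level / half the level / labeled only under AL" readout;
all are configurable and echoed to the run report.  The ratio bands are wide
relative to the %EF noise at 3 replicates and CV ≤ 0.1 (ρ SD ≈ 3–5%), which
is what makes ≥95% classification accuracy attainable in the recovery grid.

## Pipeline

Stages (`simulate`, `multivariate`, `enrich`, `specific`, `trace`, `report`)
read and write tab-separated artifacts in one output directory; the YAML
config is schema-validated with unknown keys rejected, and every stage
appends its feature counts and applied thresholds to `run_report.jsonl`,
aggregated by `report` into a stage-count ledger.  Reruns under the same
config and seed are byte-identical.  Problem sizes used by the test suite
and the acceptance script (50-feature oracle tables, a 500-feature selection
benchmark, 10-seed × 4-condition recovery grids) are chosen so the whole
analysis re-runs from scratch in seconds on one CPU while keeping every
statistical check well-powered.
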