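# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limitations of `lexmap`.

## Linguistic distance and anchor coordinates

All language-side quantities are functions of cosine similarity between
embedding vectors. The pairwise statistic is `1 − cos(v_i, v_j)` ∈ [0, 2];
the coordinate statistics are differences of cosines against the four
cardinal anchor words, `cos(v, North) − cos(v, South)` (latitude) and
`cos(v, East) − cos(v, West)` (longitude), each bounded by ±2. Both are
invariant to positive rescaling of any vector, so whether a pretrained
space is length-normalised is irrelevant to every downstream number.

Labels resolve against the embedding store byte-exactly (no case folding,
no unicode normalisation) because pretrained spaces distinguish case and
multi-word labels keep their internal spaces. A label missing from the
store is composed the way fastText composes unseen words: the label is
wrapped as `<label>`, its character n-grams of length 5 (the `minn=maxn=5`
default matches the pretrained CBOW spaces this mirrors) are hashed with
32-bit FNV-1a (offset basis 2166136261, prime 16777619) into a bucket
table, and the bucket vectors are **summed**. A `mean` aggregation flag
exists for replicating query tools that average; the two differ only by a
positive scalar, which cosine removes. The whole wrapped word is not added
as an extra token — only n-gram buckets are modelled. Degenerate labels
that produce no n-grams yield a zero vector with a warning, and every
cosine rejects zero-norm input explicitly rather than emitting NaN.

Anchor words are configuration, not code: a JSON table ships with
English/German/Spanish/Italian/French direction words as editorial
defaults, queried lowercase by default (they are common nouns), and both
the table and the casing are overridable. Anchor labels resolve by the same
exact-then-subword policy as station labels.

## Geography

Distances are spherical great-circle (haversine) on the IUGG mean radius
6371.0088 km. The radius is a parameter: the upstream convention a given
dataset was produced with may differ, and all tests validate against closed
forms rather than any package's per-pair output. Station pairing is
within-city, each unordered pair exactly once, in lexicographic id order,
so tables regenerate byte-identically. Stations listed once per line in raw
exports are deduplicated on (name, city). Within-group z-scores use the
sample (n−1) standard deviation and refuse constant or singleton groups.

## The distance model

Every analysis row is a station pair, so observations sharing a station are
correlated. The model is a Gaussian LMM with two *crossed* random
intercepts,

    y = Xβ + Z₁u₁ + Z₂u₂ + ε,  u₁ ~ N(0, σ₁²I), u₂ ~ N(0, σ₂²I), ε ~ N(0, σₑ²I),

with the pair's first and second station as the two grouping factors and
`1 + ling_dist (+ city + ling_dist:city)` as fixed effects. Estimation is
REML with the deviance profiled over the variance ratios γₖ = σₖ²/σₑ²: for
fixed (γ₁, γ₂) the fixed effects are GLS and σₑ² is closed-form, so the
problem is a 2-D search. The Woodbury identity reduces every evaluation to
one Cholesky of the q×q matrix G⁻¹ + Z′Z (q = number of intercept levels),
making 40k-pair tables cheap.

Numerics:

* the profiled deviance is minimised by Nelder-Mead over (log γ₁, log γ₂)
  from up to 10 deterministic starting points (`n_restarts`, default 10;
  the surface is unimodal in practice and fewer restarts give identical
  optima, so replicate-heavy simulations pass a smaller value);
* the three boundary candidates — each single-factor model and the OLS fit
  — are always evaluated; single-factor candidates are refined by
  root-finding the *analytic* REML score along that axis, because near the
  optimum the deviance is flat to machine precision and derivative-free
  search cannot localise variance components to the 1e−8 level the
  closed-form (balanced one-way ANOVA) comparisons require;
* variance ratios below 1e−6 are snapped to zero and flagged as boundary
  fits, not errors; when both components hit the boundary the fit is
  exactly OLS.

Inference is Wald (z on coefficients, χ² on term blocks) or
likelihood-ratio (with automatic ML refit when requested on a REML fit).
F tests with approximated denominator degrees of freedom
(Satterthwaite/Kenward-Roger) are deliberately not implemented: at the
sample sizes of these analyses (thousands to tens of thousands of pairs)
Wald/LRT and the F approximations coincide to the digits reported, and
approximate-df machinery for crossed designs is a project of its own. This
is the one intentional inferential deviation from the lme4-style output the
pipeline otherwise mirrors. Per-group *simple slopes* are linear contrasts
of the coefficient vector (reference slope plus the group's interaction
contrast) with delta-method SEs; they are invariant to the contrast
reference level. Standardised coefficients are b·sd(x)/sd(y).

## The coordinate models

`z_geo_lat ~ ling_lat × city` (and longitude likewise) is OLS with
sum-to-zero group contrasts, 2G parameters for G cities, marginal
(Type-III-style) F tests, and the same simple-slope machinery (t-based).
Treatment coding is available behind a flag for coefficient-level
replication against software that reports reference-level slopes.

## Schematic-map calibration

Digitized map exports (`label,x,y` pixel tables) are calibrated by
least-squares affine transform fitted on control points — by default every
station present in both the pixel table and the station list. An affine
map absorbs translation, rotation, anisotropic scale, shear, and the
digitizer's downward-pointing y axis (a negative axis coefficient); what it
cannot absorb is the schematic distortion itself, which is exactly the
quantity under study. Three non-collinear controls interpolate exactly;
collinear controls are a hard error.

Map distances default to planar Euclidean in the calibrated frame — the
defensible metric for a flat diagram. A `lonlat-compat` mode instead feeds
the calibrated (x, y) into the spherical formula as (lon, lat), mirroring
the replication convention of running a geographic distance routine on map
coordinates; its absolute scale is arbitrary, so only standardised or
correlational summaries of it are compared. In the type-comparison model
(`z_dist ~ ling_dist × type`), distances are z-scored within type
(geographic vs map) before stacking, so the two distance scales are
commensurable; a pooled-standardisation flag exists.

## The synthetic generator

`SynthConfig` defaults are the study conditions for all tests: a single
city of 120 stations uniform on a ±0.15° square (≈33 km span, a realistic
metro footprint), embedding dimension 50, spatial-signal weight
`alpha = 0.6`, shared-base weight `c = 3`, station noise `sigma = 0.1`,
anchor noise `tau = 0.05`, polysemy probability 0.1, and a 25% share of
two-word station names (exercising the subword path). Station vectors are

    v_k = normalize( c·u0 + a_k·(λ_k·uN + φ_k·uE) + σ·ε_k ),

with u0, uN, uE mutually orthonormal latent directions, (λ, φ) the planar
coordinates rescaled to [−1, 1], and ε standard normal scaled by 1/√dim.
The shared base direction is what lets *cosine* distance encode planar
proximity: without it, normalisation erases radial information and
distances would be unrecoverable by construction. Polysemy contamination
multiplies a station's signal weight by 1/10 rather than zeroing it — a
name dominated by non-geographic meanings is weakly, not un-, informative.
Anchors are noisy antipodal copies of the axes; anchor noise uses the same
1/√dim scaling as station noise for unit consistency. All randomness flows
from one root seed through named substreams (city, embedding, anchors), so
identical configs are bit-identical and components can be varied
independently.

What the generator does *not* emulate: corpus frequency effects (rare
stations having noisier vectors), heteroscedastic noise across cities,
non-orthogonal cardinal axes, and any actual lexical content of names —
names are arbitrary pronounceable strings, so subword composition is
exercised mechanically but carries no semantics. Passing recovery tests
therefore show the pipeline is correct and well-calibrated *given* spatially
informative embeddings; they cannot show that any real corpus is spatially
informative.

One scale effect worth knowing: the raw distance-model slope (km per unit
cosine distance) is *not* monotone in `alpha`, because the spread of the
cosine distances grows roughly linearly with the signal weight while the
covariance grows with it too — the slope peaks at small alpha and then
decays like 1/alpha. The standardised slope (equivalently the correlation)
is the monotone recovery measure, and the monotonicity tests use it.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` choose sizes that keep full runs
in minutes while leaving Monte-Carlo error well below the asserted margins:
variance-component recovery uses fully crossed 60×60 designs (200
replicates in the suite, 60 in the script), pipeline recovery uses
120-station cities, null calibration 100 seeds of 60-station cities, and
the Wald-calibration check 400 simulated two-city fits. The pair-count and
degrees-of-freedom identities are exact at the five real network sizes
(175, 265, 241, 107, 295 stations).

## Known limitations

* Random intercepts only; no random slopes or non-Gaussian responses.
* The two crossed factors must be distinct labels per row (pair data
  guarantees this; fully crossed simulations should namespace the factors).
* Affine (not projective) calibration; strong perspective distortion in a
  digitized image would alias into apparent schematic distortion.
* The shipped anchor translations are editorial defaults; replicating a
  specific published analysis requires supplying its exact anchor words and
  casing.
* `lonlat-compat` distances inherit the arbitrary scale of the digitization
  and are only meaningful after standardisation.
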