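# Methods

## The three-pool transfer model

The model tracks one metabolite at a time through three bulk,
arbitrary-unit pools: the phytoplankton endometabolome `P`, the dissolved
exometabolome `E` and the bacterial endometabolome `B`. Fluxes are

* `N = n_scale · I(t)` — biosynthesis proportional to irradiance. `I(t)` is
  a half-cosine: `peak · cos(π(clock − peak_time)/photoperiod)` within half
  a photoperiod of the peak, zero otherwise (defaults: 150 µmol photons
  m⁻² s⁻¹, 16 h, peak at noon). A `constant` shape exists for steady-state
  analysis.
* `T = t_frac · P` — allocation of endometabolites to biomass and energy,
  first-order.
* `R = r_diff · (P − E)` — diffusive release along the concentration
  gradient; negative values (back-diffusion) are permitted.
* `U = u_vmax · E/(u_km + E)` — Michaelis–Menten bacterial uptake, forced
  to zero during the axenic phase.
* `C = c_frac · B` — first-order catabolism. `C` influences only `B`,
  which is never compared to data, so fitting is insensitive to `c_frac`;
  default grids carry a single value for it.

Active mechanisms: `o` multiplies `N` by `exp(−o_decay·(clock −
peak_time))` after the peak only (irradiance is zero after dusk, so the
attenuation effectively acts from noon to dusk); `h` adds `h_coef · N` to
`R`; `b` multiplies `N` by `b_factor` from inoculation onward. With
`o_decay = 0`, `h_coef = 0`, `b_factor = 1` every variant reproduces the
base trajectory bitwise, which the tests assert.

Only the quoted process definitions constrain these functional forms; the
specific parameterisations (linear irradiance coupling, first-order
fractions, additive h, exponential o, multiplicative b) are the minimal
forms consistent with them. Each lives behind a named function
(`production`, `release`, `uptake`) so alternates can be swapped.

### Integration and protocol

Explicit forward Euler at `dt = 0.1 h` for 10 simulated days from
`P = E = B = 0`: 6 axenic days (B and U pinned to zero), instantaneous
inoculation at day 6, and comparison of the final 2 days against the
experimental window. Sampling maps the 9 experimental timepoints (6-h
spacing, first sample at midnight) onto exact grid indices. A pool driven
negative by a step is clamped to zero and the event logged; mass balance
(`P+E+B = Σ(N−T−C)dt` in the absence of clamping) holds to 1e-9 relative
and is tested over random parameter sets. Correlation-based fitting is
scale-invariant, so pool magnitudes are arbitrary; population growth is not
modelled inside the dynamics. Halving `dt` moves sampled values by <1 %
at default parameter magnitudes.

A vectorised integrator advances thousands of parameter sets
simultaneously (one numpy-array state per pool) and is bitwise-identical
to the scalar path; an exhaustive sweep of all 8 variants' default grids
(~15,000 simulations) takes a few seconds.

## Grid-search fitting and variant selection

For each variant, the Cartesian product of per-parameter value lists is
simulated; modelled P and U at the 9 sample times are correlated against
the replicate-averaged experimental metabolite and transcript series
(Pearson r, two-sided p from the t transform on n−2 df). A parameter set
is saved only when both correlations are significant at p < 0.05 — the
dual screen is what forces mechanisms: e.g. no passive parameterisation
can produce a rising P and a noon-peaking U simultaneously. No
multiplicity correction is applied across the grid (the screen is a
filter, not an inference).

Default grids are small and log-spaced (240 base combinations): allocation
and release rates span 0.01–2 h⁻¹, from multi-day relaxation (inoculation
transients persist through the comparison window, producing monotone
trends) to sub-hour tracking of irradiance; uptake spans linear
(`u_km ≫ E`) to saturated (`u_km = 0.1`, where nightly exhaustion of E
thresholds U into a noon spike). Active-term lists exclude neutral values
so each variant is a genuinely distinct mechanism, and the default
`b_factor` list contains only amplification (>1), treating the bacterial
response as increased production — the direction supported by co-culture
versus axenic comparisons; suppressive values can be supplied through
custom grids. Grid contents are pure configuration.

Variants are ranked by the mean of the two correlations of their best
record, adjusted for the number of active terms k (n = 9 samples). Two
adjustment conventions are implemented and always reported explicitly:

* `standard`: `1 − (1 − r)(n − 1)/(n − k − 1)` — the conventional
  adjustment; identity at k = 0, fixed point at r = 1, mild penalty
  (~(1−r)·k/7).
* `printed`: `1 − (1/r)(n − 1)/(n − k − 1)` — a much harsher parsimony
  rule under which a k-term variant overtakes a fitting base model only
  when the base correlation is below `(n−1−k)/(n−1)` times the variant's;
  in effect, "the base model wins whenever it fits well". It diverges for
  r → 0⁻ and rewards negative correlations, so only variants with a
  positive best mean r are eligible under it.

Ties break toward fewer active terms, then lexicographic variant id. The
mechanism-discrimination study uses the printed mode because the harsher
penalty is what yields the qualitative pattern the study design targets;
the API default remains `standard`.

## Synthetic-data generator

The generator emulates the reference experiment so every stage can be
validated against known truth: 9 timepoints × 6 h × 3 replicates starting
at midnight; diatom density growing exponentially from 0.87×10⁵ to
1.9×10⁵ cells mL⁻¹ with optional lognormal replicate scatter; 281
metabolite peaks allocated 102/73/59/47 across four archetypes by
largest-remainder rounding; 4,278 genes across three archetypes with
shares proportional to 3,294/756/271 (allocated 3261/749/268 — the
reported cluster sizes sum to 4,321, so they are treated as proportions of
the 4,278-gene genome).

Archetype shapes (Z scale): M-1/M-2 are linear trends (±3 Z units over
48 h) plus a small noon ripple (amplitude 0.2); M-3/M-4 and G-1 are
truncated 24-h cosines (`max(cos, 0)`) peaking at 18:00 / 12:00 / 12:00;
G-2 adds to G-1 a decaying component `1.2·exp(−t/9 h)` elevated at the
first samples; G-3 is the decaying component alone. Metabolite replicate
noise is additive Gaussian on the Z scale, default SD 0.3 — a free
parameter of the generator, not calibrated to any deposited dataset, chosen
as a visible-but-not-dominant within-timepoint scatter.

Transcript truth assigns each gene a lognormal abundance (σ = 1.2) and a
lognormal diel-amplitude factor (σ = 0.6; genes span weak to strong diel
regulation, without which no gene could occupy the "masked" quadrant), then
rescales each timepoint so summed transcripts per cell equal the diel phase
means (58 at night, 95 mid-morning, 114 at noon, 42 mid-afternoon). Reads
are drawn multinomially per sample over {rRNA, spike-1, spike-2, genes}
with probabilities proportional to molecule masses: rRNA mass is set for a
17.5 % read share, and the spike copies added (equal for the two
standards) are solved by 1-D root finding so the across-sample mean
expected spike share of mRNA reads is exactly 2.2 % (per-sample gene mass
varies with the phase means, so a single-sample closed form would be
biased). Replicate variation in reads is multinomial only.

What the generator does **not** emulate: biological replicate variance in
transcripts beyond sampling noise, peak overlap or chemical-shift artefacts
in NMR data, gene–gene correlation structure, bacterial population growth,
and any coupling between the metabolite and transcript tables beyond their
shared design. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative assumptions, not performance on
real co-culture data.

## Quantitation and fold-change analysis

Transcripts per cell: `tpc(g,s) = reads(g,s)/Σ spike reads(s) × Σ copies
added / cells extracted(s)`, with samples lacking spike reads excluded and
reported (never imputed) and a per-sample diagnostic comparing the two
standards' read ratio to their copy ratio. The estimator is
depth-invariant and inversely proportional to cells extracted; on
default-depth synthetic data it recovers truth within ~1.5 % mean relative
error for genes with ≥50 expected reads.

Noon:night comparisons use all noon samples against the two cycle-closing
midnights (t24, t48). The experiment-initial midnight precedes full
bacterial drawdown of pre-accumulated metabolites and carries
systematically elevated inventories (the same feature the G-2/G-3
archetypes encode), so it is not a steady-state night reference; including
it inflates within-group variance and hides the masked quadrant entirely.
Missing replicates shrink a group (available-case means). Absolute fold
change is computed on tpc, relative fold change on per-sample
shares `tpc(g,s)/Σ_g tpc(g,s)`; both axes use two-sided Welch tests on
log₂ values (the reference analysis does not state its test; Welch is the
conservative default) with Benjamini–Hochberg correction per axis, and
quadrant classes (concordant-up/-down, masked-up/-down, null, undefined)
follow significance and direction on both axes.

Z-scoring uses the n−1 denominator throughout; zero-variance features are
emitted as zeros and flagged.

## Clustering

Weighted fuzzy c-means on replicate-averaged Z profiles, fuzzifier m = 2,
best of 5 random restarts per candidate c. Variance sensitivity enters as
per-feature weights `w_i = 1/(1 + s_i²)`, with `s_i²` the mean
within-timepoint replicate variance on the Z scale; weights scale each
feature's contribution to the objective and the centroid update (the
membership update is weight-free). This weighting is this package's own
concrete choice for "variance-sensitive" clustering. Cluster number is
selected by minimising the Xie–Beni index
`ΣΣ u_ij^m‖x_i−v_j‖²/(n·min‖v_j−v_j'‖²)` over the candidates; the minimum
centroid distance is computed for every candidate and used to discard
degenerate solutions (near-duplicate centroids, which would win XB through
a vanishing denominator) rather than as a separate elbow detector. Ties go
to smaller c. Hard labels require a maximum membership above 0.5, else
"n.a." — the published footnote reads as the opposite direction, which
contradicts the usual convention; it is interpreted here as "no membership
exceeding the threshold".

## Rhythm detection

A deliberate stand-in for umbrella-alternative rhythm detectors: ordinary
least squares of `mean + A·cos(2πt/24) + B·sin(2πt/24)` on the
replicate-level values, statistic = variance explained, null distribution
by permuting timepoint labels independently within each replicate
(`p = (1 + #{perm ≥ obs})/(1 + n_perm)`, default n_perm = 199). Phase is
`atan2(B, A)` mapped to clock hours; phase classes: night [21,3), morning
[3,9), noon [9,15), mid-afternoon [15,21). The test is exact
(super-uniform under the null, verified over 1,000 null features) but only
powered against roughly sinusoidal alternatives — adequate for the
generator's truncated-cosine shapes, weaker for sharp asymmetric waveforms.
Zero-variance series get p = 1; coverage below two full periods triggers a
warning.

## Pipeline and reproducibility

All stages read/write tab-delimited UTF-8 tables with sample columns
`t{HH}_rep{j}` (hours from the first sample) and a reserved `cell_count`
row; ground truth is emitted as JSON plus TSV sidecars. Every stochastic
stage receives a seed spawned from one master seed, and rerunning a config
reproduces outputs byte-identically. Default test/problem sizes (full
experiment tables, 240–6,480-combination grids, 20-seed simulation
studies) keep the complete suite and studies to a few minutes on one core.

## Known limitations

* Uptake capacity is constant after inoculation; whether it should scale
  with bacterial growth over the co-culture days is an open modelling
  question.
* Each metabolite/gene pair is fitted independently; no joint inference.
* The fitted grids are far coarser than an exhaustive production sweep
  would be; grid contents are configuration, and conclusions about
  mechanism families (not point estimates) are the intended output.
* The printed adjusted-correlation formula returns 0 for a perfect fit and
  is undefined at r = 0; it is retained verbatim as one of two explicit
  conventions rather than silently "fixed".
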