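# dielflux

Tools for studying diel (day/night) metabolite transfer between a
phytoplankton cell and a co-cultured heterotrophic bacterium — the kind of
model community used to ask *how* labile organic carbon leaves a diatom:
by passive diffusion alone, or through active release mechanisms.

The package is aimed at researchers analysing paired time-series of
phytoplankton endometabolite inventories (e.g. NMR peak intensities per
cell) and bacterial uptake-gene transcription (absolute transcripts per
cell), and at modellers who want a small, fully testable mechanism-selection
pipeline for such data.

## The model

Three pools evolve under forward-Euler integration (0.1-h steps over a
10-day protocol, the first 6 days axenic):

```
dP/dt = N − T − R        P  phytoplankton endometabolite pool
dE/dt = R − U            E  dissolved exometabolite pool
dB/dt = U − C            B  bacterial endometabolite pool
```

with `N = α·I(t)` light-driven biosynthesis (I is a half-cosine diel
irradiance, 16 h photoperiod, 150 µmol photons m⁻² s⁻¹ peak at noon),
`T = t_frac·P` allocation to biomass, `R = r_diff·(P − E)` diffusive
release, `U = Vmax·E/(Km + E)` Michaelis–Menten bacterial uptake, and
`C = c_frac·B` catabolism. Three optional active mechanisms extend the
base model:

* **o** — fixation–irradiance oscillation: `N ← N·exp(−o_decay·Δt)` after
  the irradiance peak (carbon fixation declines faster than light);
* **h** — homeostasis: `R ← R + h_coef·N` (release tracks production);
* **b** — bacterial response: `N ← b_factor·N` once bacteria are present.

Each of the 8 variants (base plus every subset of {o,h,b}) is fitted to a
metabolite/gene pair by an exhaustive grid sweep; a parameter set is kept
when modelled P correlates with the metabolite series *and* modelled U with
the transcript series (Pearson, two-sided p < 0.05, n = 9). Variants are
ranked by the mean of the two correlations, penalised for the number of
active terms k through an adjusted correlation (two conventions are
implemented; reports always state which was used).

Supporting analyses: spike-in–calibrated transcripts-per-cell
quantitation, per-feature Z-scoring, variance-weighted fuzzy c-means
clustering with Xie–Beni cluster-number selection, a cosinor/permutation
diel-rhythm test, absolute-vs-relative fold-change quadrant analysis, and
a synthetic-data generator that emulates the whole experiment (281
metabolite peaks in four temporal archetypes, 4,278 genes in three, diel
total-mRNA modulation, ~2.2 % spike-in and ~17.5 % rRNA reads) with full
ground truth.

## Worked example

```
$ python examples/03_fit_mechanisms.py
base:    0/240 parameter sets pass the dual p<0.05 screen
o   :    0/720 parameter sets pass the dual p<0.05 screen
h   :   11/720 parameter sets pass the dual p<0.05 screen; best mean r = 0.070
b   :    0/720 parameter sets pass the dual p<0.05 screen
oh  :   51/2160 parameter sets pass the dual p<0.05 screen; best mean r = 0.743
ob  :    0/2160 parameter sets pass the dual p<0.05 screen
hb  :   15/2160 parameter sets pass the dual p<0.05 screen; best mean r = 0.806
ohb :  105/6480 parameter sets pass the dual p<0.05 screen; best mean r = 0.843

winner: hb
```

The pair here is synthetic: a monotone-increasing endometabolite (archetype
M-1) matched with a noon-peaking uptake gene (G-1). Passive diffusion
cannot reproduce a rising endometabolite pool after inoculation — every
base-model set fails the screen — whereas variants containing the
bacterial-response term b fit both series; `hb` wins the adjusted ranking.
The other examples generate a full synthetic experiment, recover the four
metabolite archetypes by clustering (`selected c = 4`, memberships matching
the generating truth), classify their rhythms (noon vs mid-afternoon
phases), and demonstrate "masked" upregulation: genes whose per-cell
transcript count rises at noon (absolute FC ≈ 1.4) while their share of the
transcriptome falls (relative FC ≈ 0.7), an artefact class invisible to
relative-only RNA-seq analysis.

A thin CLI mirrors the library (`dielflux generate | simulate | fit |
quantify | cluster | rhythm | foldchange | pipeline`); `dielflux pipeline
--out RUN` runs every stage end to end from one YAML config and writes a
manifest for reproducibility.

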