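# Methods

## Scope and model of the experiment

`glutrace` analyzes single-endpoint stable-isotope labeling
experiments: cells are switched to medium in which glutamine or
glucose is replaced by a ¹³C/¹⁵N-labeled form, incubated ~24 h, and
measured once — media concentrations (blank vs harvest), integrated
isotopologue abundances (MIDs) of intracellular and media metabolites,
labeled-pool sizes (EIC per mg protein), bulk protein ¹³C by
combustion IRMS, and fatty-acid MIDs after a 2-day lipid labeling.
Because all readouts are fractional and taken at one late time point,
the simulator treats the labeling state as an **isotopic steady
state** and the media as **linear accumulation/depletion** in time; no
kinetic ODEs are solved. A depletion guard raises an error rather than
clamping when a flux assignment would drive a media concentration
negative within the incubation.

## Natural-abundance correction

A measured MID mixes tracer-derived label with naturally occurring
heavy isotopes of every atom. The correction matrix column j is the
expected measured MID of a molecule with exactly j tracer atoms:
shift-j delta (binomially degraded by tracer purity, default 1.0,
configurable) convolved with the natural MID of the unlabeled tracer
positions and of all other formula atoms. By default all elements of
the formula contribute (C, H, N, O, S at IUPAC terrestrial
abundances, ¹³C = 0.0107); a carbon-only mode exists for testing.
Correction solves **M**·x ≈ measured by non-negative least squares
(`scipy.optimize.nnls`) and renormalizes — NNLS rather than matrix
inversion because inversion of noisy tails produces negative
isotopologues that would otherwise need ad hoc clipping.

For the dual-isotope tracer (¹³C₅¹⁵N₂-glutamine) MIDs are indexed by
*total* nominal mass shift over the tracked skeleton (5 carbons + the
amino nitrogen for glutamate, 7 channels M0–M6). The correction matrix
for these channels assumes the labeled positions fill carbons first
and nitrogen last; since the ¹³C and ¹⁵N natural corrections differ by
<1% of channel intensity, the residual model error of this convention
is far below the 5% measurement noise, which the dual-isotope
round-trip test quantifies (≤0.005 absolute per channel, noiseless).

## The atom-mapped network

Metabolites carry explicit carbon skeletons (standard biochemical
numbering) and, where nitrogen fate matters, tracked amino nitrogens;
a metabolite with k tracked atoms has 2^k positional labeling states
(k ≤ 7 here, so full enumeration is cheap and no EMU decomposition is
needed). Reactions map every product atom to a substrate atom or to an
unlabeled source (CO₂ fixation, free ammonia, external pools). Key
maps:

- glutaminase drops the amide N; glutamine synthetase adds an
  unlabeled amide N;
- transaminases/GDH exchange the glutamate amino N with one well-mixed
  amino-nitrogen pool whose ¹⁵N fraction is itself part of the fixed
  point, diluted by an unlabeled influx (`n_influx`) from other amino
  acids — this generates ¹⁵N-only (M1) glutamate;
- oxidative 2-oxoglutarate dehydrogenase releases C1; succinate and
  fumarate are symmetric (distributions averaged with their
  carbon-reversed image after every update);
- citrate atoms 0–1 form the acetyl arm (ATP-citrate lyase returns
  them as lipogenic acetyl-CoA), atoms 2–5 the oxaloacetate part;
  reductive IDH places 2-oxoglutarate C4/C5 on the acetyl arm and adds
  unlabeled CO₂, so uniform glutamine label yields citrate M5 and,
  after ACL, malate M3 — while 1-¹³C-glutamine retains M1 on citrate
  and malate only via this route;
- malic enzyme drops malate C4; pyruvate dehydrogenase drops pyruvate
  C1; pyruvate carboxylase adds unlabeled CO₂; glycolysis uses the
  standard C1–C3/C4–C6 split;
- the proline/ornithine branch runs through
  pyrroline-5-carboxylate in both directions, with unlabeled media
  proline and ornithine diluting the intracellular pools;
- an unlabeled oxaloacetate influx (`oaa_influx`) represents
  anaplerosis from unlabeled sources (aspartate, protein turnover).
  Without it, steady-state recycling of labeled acetyl units through
  the cycle accumulates implausibly multi-labeled citrate; with it,
  the glucose tracer produces the observed M2/M3-dominated patterns.

Sink and source fluxes that close each internal mass balance are
derived automatically from the user-assigned fluxes; a derived sink
that would need to be negative raises an error naming it, and the
assembled model re-verifies production = consumption for every
internal metabolite to 10⁻⁶ of total flux.

The steady state is the fixed point of the label-balance equations,
found by Gauss–Seidel sweeps (each metabolite's distribution replaced
by the flux-weighted mixture of its producers' mapped outputs) until
the largest per-sweep L1 change falls below 10⁻¹² (default; max 5000
sweeps, error with the residual on non-convergence). Multi-substrate
reactions combine their substrates' distributions as independent
(well-mixed pools). The result is invariant under uniform flux
scaling, and agrees with an independent stochastic molecule-ancestry
simulation on small networks (test, 10⁵ molecules, 3 SE).

## Measurement emulation

The simulator's "uncorrected" MIDs are computed exactly: each
positional labeling state contributes its nominal shift convolved with
the natural-abundance envelope of the atoms it leaves unlabeled
(element-aware), truncated at the tracked-shift range; multiplicative
Gaussian noise (default CV 5%) is applied per channel and the vector
renormalized, mimicking an integrated isotopologue table. Media
glutamate mixes the pre-existing unlabeled pool (54 µM) with secreted
material at the intracellular composition; the analysis stage
deconvolves that mixture channel-wise from the blank and harvest
concentrations. Labeled pools report pool_scale × P(≥1 heavy atom);
biomass ¹³C atom percent is baseline (1.0799%) plus a term
proportional to the protein-incorporation flux times the glutamate
¹³C atom fraction, with Gaussian noise of 0.0023 percentage points
(the baseline's observed spread). Fatty-acid MIDs come from the ISA
forward model with D read off the simulated lipogenic acetyl-CoA pool
and a preset g.

Experiment geometry defaults: 0.5 mL labeling medium and 0.25 mg
protein per well, 24 h — a dense 12-well culture in reduced medium
volume, which makes the 24-h concentration changes large relative to
the 5% concentration noise (glutamine drops from 2.0 to ~0.4 mM in the
HEP-L-like condition, a depletion regime typical of hepatocyte
cultures).

What the generator does **not** emulate: metabolite identification
errors, retention-time drift, detector saturation, compartmentation
(cytosolic and mitochondrial pools are merged), isotopic
non-stationarity of slow pools, and exchange-flux reversibility beyond
the explicitly bidirectional reactions. Passing tests therefore show
that the analysis stages are correct and well-calibrated under the
stated noise model, not that they are robust to those real-data
pathologies.

## Condition presets

The three flux presets (HDF-like, HEP-L-like, PHH-like;
µmol·mg⁻¹·day⁻¹) encode the qualitative phenotypes — fibroblasts:
moderate glutamine uptake, net glutamate consumption, strong proline
synthesis, high protein incorporation, weak reductive carboxylation;
hepatocyte-like cells: doubled uptake, strong deamidation/secretion,
weak proline synthesis, stronger reductive carboxylation; primary
hepatocytes: the hepatic pattern amplified. Their magnitudes are
calibration knobs tuned once so that the packaged analysis stages
recover the study-scale fractional readouts (secreted-glutamate source
shares ≈ 71/15/14%, ≈58% re-secretion of uptake, 14-fold proline
contrast, 53% labeled-lipogenesis contrast, 70% biomass-enrichment
excess, 2-fold uptake contrast); no measured dataset stands behind the
individual flux values, and downstream code never reads the target
numbers — they emerge from simulation plus analysis.

## ISA

Newly synthesized fatty-acid molecules draw each of their n acetyl
units from the lipogenic pool: with probability D the unit is
tracer-derived (nominal shift s = 2 for uniformly labeled acetyl, 1
for 5-¹³C-glutamine-derived acetyl), and all carbons not fixed by the
tracer — including those of unlabeled units — carry natural ¹³C, so
D = 0 reduces exactly to the natural MID of the intact molecule. The
observed (uncorrected) MID is (1−g)·natural + g·new. Fitting is
bounded least squares on (D, g) ∈ [0,1]², multistarted from a 5×5
lattice, with residuals scaled by expected channel intensity because
abundance noise is multiplicative; replicates are stacked into one
joint residual by default (per-replicate mode available). The spread
of (D, g) across cost-tied starts is reported as an identifiability
diagnostic: at g ≈ 0 (or D ≈ 0) the other parameter is undetermined
and the spread flags it. Condition contrasts are reported for D, g and
D×g; D×g — the fraction of acetyl units that are both newly
incorporated and tracer-derived — is the package's reading of a
"labeled synthesis rate", since neither parameter alone captures it.

## Rates, apportionment, utilization

Exchange rate = (blank − harvest) × volume / protein / days, positive
for uptake; per-day normalization always uses 24 h. Replicate-level
rates are averaged before any ratio is formed. The glutamine-derived
share of secreted glutamate is M5+M6 of the corrected, deconvolved
secreted-glutamate MID — **M1 (¹⁵N-only) is deliberately excluded**,
because its carbon skeleton is not glutamine-derived; this is the
easiest bookkeeping mistake in the dual-isotope design and is pinned
by a dedicated test. The glucose share is M2+M3 from the
¹³C₆-glucose experiment. Each share is computed within its own
experiment; combining them assumes equal net secretion across the two
experiments (warning at >20% disagreement), and the remainder is
attributed to other sources, floored at zero with a warning.

## Untargeted screen and power

Features present in every sample of at least one group survive the
presence filter (no imputation — missingness handling mirrors that
single rule). The volcano screen Welch-tests log2 intensities
feature-wise, adjusts by Benjamini–Hochberg, and calls significance
jointly on |log2 FC| > log2(2) (on raw group-mean ratios) and adjusted
p < 0.005. Monte-Carlo power analysis simulates two-group normal
datasets at given means/SDs for increasing n and returns the smallest
n whose empirical Welch-test power reaches the target; it matches the
closed-form noncentral-t calculation (n = 7 at standardized effect
1.70, α = 0.05, power 0.80).

## Numerical choices and degenerate inputs

- Normalization tolerances: 10⁻⁹ on the simplex for internal vectors;
  [0.98, 1.02] for spectra read from CSV.
- All-zero measured MIDs, zero internal-standard areas, zero citrate
  concentrations, groups with fewer than 2 replicates, secretion
  exceeding uptake: errors, not silent repairs.
- Per-feature tests with fewer than 2 finite values per group yield
  NaN p-values and are excluded from BH and from significance.
- Every random stage derives its stream from one seed via
  `SeedSequence` with crc32-hashed stage tags (stable across
  processes); identical seeds give bit-identical outputs.

## Problem sizes

The test suite and the acceptance script run the full network
(≤ 2⁷ states per metabolite, ~47 reactions) to steady state in tens of
milliseconds; the simulated studies use the study-scale replicate
counts (n = 6–8 per group, 858-feature tables), so a complete run of
suite plus acceptance finishes in well under a minute on one CPU.

## Known limitations

- Merged compartments mean the αKG/citrate concentration ratio and
  reductive-flux readouts cannot capture cytosol-specific effects.
- The steady-state assumption overstates multi-pass labeling for slow
  pools; the unlabeled anaplerotic influxes compensate at the level of
  the fractional readouts but are not kinetic fits.
- The dual-isotope correction matrix uses the carbon-first labeling
  convention (exact for all single-isotope tracers).
- ISA assumes a single well-mixed lipogenic acetyl-CoA pool and no
  elongation/desaturation beyond the modeled chain.
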