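# Methods

This note documents the models and procedures implemented in `taushield`,
the assumptions behind them, the defaults of the synthetic-data generators,
and the numerical choices made where the design was genuinely open. All
residue numbers are absolute 1-based positions in the 2N4R (441-residue)
isoform of human tau; the repeat-domain construct (tau RD) spans residues
244–380 and its sequence ships with the package, with lysine positions
computed from it rather than hard-coded.

## Cross-link contact maps (`xlms`)

**Inputs.** Post-search cross-link identification tables (one row per
identified lysine–lysine pair per replicate, with QC metrics). Upstream
peptide-spectrum matching and FDR estimation are out of scope; an optional
`decoy` column is dropped with a logged count.

**Validation filters.** A record is retained iff *all* hold: ld-score
strictly greater than 25; mass error within [−2.2, +3.8] ppm (bounds
inclusive — strictness at the ppm bounds is a convention and the inclusive
reading is adopted); %TIC strictly greater than 10; both peptide lengths at
least 6 aa; and each peptide independently carries at least 4 assigned
fragment ions or at least 3 contiguous ones. Score and %TIC are strict
inequalities as printed; peptide length is a minimum.

**Consensus.** Within one condition and temperature, a residue pair enters
the consensus when present in at least `required_count` of `n_replicates`
replicates (default 5 of 5). A pair identified by several rows in one
replicate counts once, with that replicate's spectral frequency taken as the
maximum row `nseen` (frequency is a per-replicate property). The consensus
`mean_frequency` averages `nseen` over the replicates in which the pair
appears; at the 5-of-5 default this equals the average over all replicates.

**Sectors.** N-term means both residues in 243–310, C-term both in 311–380,
N–C otherwise; the boundary is immediately after the VQIVYK motif, so
residues 306–310 of the motif fall in the N-term sector and 311 opens
C-term. The R2R3 flag marks contacts with one residue in 275–305 and the
other in 306–336 — the inter-repeat interface whose stepwise loss with
temperature is the heat-denaturation readout. Counts conserve:
N-term + C-term + N–C = total.

**Differential retention.** For each sector and temperature the table
reports the within-genotype fraction retained relative to the 37 °C
baseline and the mutant/wild-type count ratio at matched temperature; 0/0
is reported as undefined (NaN), x/0 with x > 0 as infinity.

**DSS mass arithmetic.** The d12−d0 spectral-pair difference is twelve
deuterium-for-hydrogen exchanges, 12·(m_D − m_H) = 12.075321 Da; the light
cross-linker shift is the suberate bridge C₈H₁₀O₂ = 138.068080 Da; the
hydrolyzed mono-link adds one water, 156.078644 Da. Atomic masses come from
pyteomics' NIST table. The second (quenched) mono-link mass, 155.096428 Da,
is carried as a configured constant: it is not derivable from a simple DSS
adduct (an ammonia-quenched amide computes to 155.094629 Da).

## ThT kinetics (`kinetics`)

**Processing.** Blank wells are averaged pointwise (linear interpolation if
grids differ) and subtracted; negative post-subtraction values are retained.
A condition is fitted only if its raw maximum exceeds twice the mean blank
background (the 2:1 gate); failing traces are reported as having no
detectable ThT signal change. Traces are normalized per condition so the
maximum of the mean replicate curve is 1; time is in hours throughout.

**Model.** The four-parameter Boltzmann sigmoid
y(t) = F₀ + A / (1 + exp((t½ − t)/τ)). This is the simplest
sigmoid exposing the half-maximal transition time directly as a parameter;
mechanistic nucleation–elongation models are out of scope. Initialization
is deterministic and data-driven: F₀ = min y, A = max y − min y, t½ = the
half-max crossing of a 5-point median-smoothed trace, τ = 10% of the time
span. Fits use bounded trust-region least squares; non-convergence, a
transition outside the observed window, or an amplitude unresolved above
the residual noise (A < 3·SD of residuals) are reported as non-converged
with diagnostics rather than raised.

**Uncertainty.** The default 95% CI on t½ is asymptotic (parameter
covariance, t-distribution on n − 4 df); a seeded residual bootstrap
(B = 1000) is available for non-Gaussian noise. Replicates are fitted
separately and summarized as mean t½, replicate SD, and a pooled t-based
CI — matching the average-of-triplicates presentation — rather than fitting
the pooled mean curve. Empirical coverage of the asymptotic CI, measured by
the test suite over 1000 noisy synthetic triplicates (5% amplitude noise,
5-minute grid, 48 h span), falls within the 90–98% band.

## Chimera panels (`chimera`)

The repeat-2 leading strand ²⁹⁵DNIKHVPGGGS³⁰⁵ and its repeat-1 analogue
²⁶⁴ENLKHQPGGGK²⁷⁴ differ at positions 1, 3, 6 and 11 of the 11-mer.
`enumerate_chimeras` builds all 2⁴ = 16 combinations, appends the VQIVYK
core (17-mers total), and applies fixed mutations afterwards — by default
P→L at leading-strand position 7, the P301L substitution in the repeat-2
frame. Members are ordered by binary counting over the ascending differing
positions, so the two parent-derived peptides are first and last; a fixed
mutation at a differing position is rejected as conflicting. Deletion
variants are encoded as explicit sequences, not generated combinatorially.

The kinetic-regime classifier encodes the observed trend — roughly an order
of magnitude of aggregation delay per repeat-1 substitution: 0–1
substitutions aggregate in hours, 2 in tens of hours, 3 in hundreds of
hours, and all 4 show no signal within a week (censored).
`fit_delay_trend` quantifies the trend as the least-squares slope of
log₁₀(t½) against substitution count, excluding censored members with a
logged count. Per-chimera half-times are supplied by the user or the
generators; they are not packaged.

## Ensemble geometry (`geometry`)

**Representation.** CA-only conformations over a common ascending residue
set; all-atom support is out of scope. Ensembles carry optional
non-negative statistical weights (e.g. metadynamics reweighting factors
supplied externally — never computed here).

**Superposition and RMSD.** Kabsch superposition via SVD with the
determinant sign correction, so reflections are never applied and mirror
images retain non-zero RMSD. Coincident (rank-0) point sets raise;
collinear sets are deliberately permitted — the residual rotation about the
line axis is a gauge freedom that does not change the RMSD, and the
extended-chain limit of the hairpin collective variable depends on it. An
independent cross-check against MDAnalysis' RMSD routine runs in the test
suite.

**Collective variable and free energy.** The hairpin-deviation CV is the
superposed CA RMSD over residues 295–311 to an ideal antiparallel hairpin
(3.8 Å strand rise, 5.0 Å strand separation, 4-residue turn) — a documented
convention, since no reference structure is deposited. CV samples are
histogrammed (default bin width 0.5 Å) and Boltzmann-inverted,
F_i = −k_B·T·ln p_i with k_B = 0.0083145 kJ/mol/K and T defaulting to
300 K, min-shifted to zero. Zero-probability bins are flagged unpopulated
(NaN), never assigned finite values. Per-bin 95% CIs come from a seeded
bootstrap over samples (percentile half-widths).

**Basins.** Local minima are sought over populated bins, with unsampled
neighbours acting as infinite walls. To keep Poisson count jitter on a
basin shoulder from being reported as a basin, non-global minima must be
separated from the global one by at least 0.5 kJ/mol of barrier (about
0.2 k_BT at 300 K — far above the count-noise scale of well-sampled
histograms, well below gaps of physical interest; configurable). The
report gives the two lowest basins, their free-energy difference, and the
barrier along the profile; if the saddle region was never sampled the
barrier is reported as unresolved (NaN) rather than estimated from tail
bins. Fewer than two basins yields a single-basin report, not an error.
Experimentally reported basin energetics for this system (gaps of a few
kJ/mol between collapsed and extended states) derive from microsecond-scale
metadynamics and are not desk-reproducible; they set the scale of the
synthetic two-basin constructions used in testing, where a 5 kJ/mol
injected gap is recovered within 0.5 kJ/mol at 50,000 samples.

**Clustering.** k-medoids on the pairwise RMSD matrix (alternating
assignment/update, 10 seeded restarts, best objective kept — a standard
choice where no particular algorithm is mandated), reporting medoids and the median
within-cluster pairwise RMSD. Exhaustive search verifies the k = 1 medoid
on small inputs in the tests.

## FRET seeding (`fret`)

**Compensation.** Sequential, in the order the channels are acquired:
YFP′ = YFP − s_cy·CFP, then FRET′ = FRET − s_cf·CFP − s_yf·YFP′. The
operation is linear in the event intensity vector and exactly inverts the
generator's spill model. Spill fractions are estimated from single-positive
controls as the median acceptor/donor ratio above a donor-intensity floor.

**Gating.** FRET gates are conventionally drawn by eye in cytometry
software; both gates are parameterized here with negative-control
calibration as the default placement rule. The triangular FRET-vs-CFP gate's lower edge follows the
negatives' FRET-on-CFP regression slope, raised so that at most
1 − quantile (default 0.1%) of negative events fall above it; the apex sits
far above the observed intensity range so the triangle approximates the
half-band above the boundary across the observed CFP range. The false-FRET
boundary, calibrated on YFP-only cells, excludes events whose FRET signal
is attributable to YFP emission (below a linear quantile boundary in
FRET-vs-YFP). At quantile 1.0 the edge sits strictly above the most extreme
calibration event, so no negative classifies positive.

**Readout.** Integrated FRET density = percent positive (0–100 scale) ×
median compensated FRET of positives (MFI = median); all three fields are
exactly zero when no event is positive. Percentages are over all supplied
events; viability subsetting is upstream of these tables.

## Synthetic-data generators (`simulate`)

All generators are deterministic under a seed, write ground truth to
sidecar tables that no analysis stage reads, and emit the exact formats the
readers consume (TSV/CSV/multi-model PDB/FASTA).

- **Cross-links.** True contacts are lysine pairs of the packaged tau RD
  sequence, included with per-sector base probabilities (defaults 0.5 /
  0.5 / 0.3 for N-term / C-term / N–C) and per-replicate Bernoulli survival
  per (sector, temperature); defaults mirror the observed pattern — C-term
  contacts nearly temperature-stable (1.0/0.95/0.9 at 37/50/75 °C), N-term
  and N–C contacts progressively lost (1.0/0.85/0.7 and 1.0/0.7/0.5), with
  a genotype multiplier damping mutant N-term/N–C survival when heated.
  Five replicates at 37/50/75 °C match the experimental design. QC fields
  of true links are drawn inside all filter bounds; decoys fail exactly one
  randomly chosen criterion, drawn just outside its bound. `nseen` is
  1 + Poisson (mean 4). Five-of-five consensus retention under survival p
  follows p⁵, which the tests check against binomial bounds.
- **ThT.** Boltzmann sigmoid plus Gaussian noise on a 5-minute grid
  (matching the scan interval), triplicate by default, with three blank
  wells at baseline. Gaussian noise is the simplest model consistent with
  plate-reader fluctuations; real plates also drift and photobleach, which
  these traces do not emulate — passing recovery tests therefore
  demonstrates correctness of the fitting machinery, not robustness to all
  instrument artifacts.
- **Ensembles.** Mixtures of the ideal hairpin and an extended 3.8 Å-rise
  chain over residues 295–311 with isotropic Gaussian coordinate noise
  (default 0.3 Å). These are geometric archetypes, not physical
  conformers; they give the CV a known bimodal structure with separation
  far above the noise (the ideal extended-vs-hairpin CV is ≈ 18.5 Å).
- **Flow events.** Log-normal channel intensities (CFP median 200, YFP
  300, negative FRET 30, positive FRET 500, σ 0.3–0.4), spill applied
  linearly (defaults 10% CFP→YFP, 15% CFP→FRET, 5% YFP→FRET), 20,000
  events per replicate as in the experimental protocol. Doublets, debris
  and detector saturation are not emulated.

## Problem sizes used in the checks

The acceptance script refits noiseless traces on the native 5-minute grid
over 48–120 h windows (577–1441 points). The test suite uses 50,000-sample
CV sets for free-energy recovery, 1000 triplicates for CI calibration,
20,000-event tables for FRET recovery, and ~210-link tables (all lysine
pairs) for consensus statistics — sizes at which the binomial and bootstrap
bounds quoted above are meaningful while the whole suite runs in well under
a minute of compute per module.

## Known limitations

- The Boltzmann sigmoid is a phenomenological choice; very asymmetric
  aggregation curves (long lags with slow plateaus) may be better served by
  Gompertz-type models, whose half-times can differ for broad transitions.
- The consensus treats replicates as exchangeable; batch effects between
  replicates are not modelled.
- The FES bootstrap resamples CV values as i.i.d.; autocorrelated
  trajectory samples would need block bootstrapping for honest CIs.
- Basins shallower than the prominence threshold (0.5 kJ/mol by default)
  are deliberately not reported.
- The gating triangle approximates a half-band; events with CFP beyond ten
  times the calibration range fall outside the gate by construction.
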