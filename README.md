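# taushield

Quantitative analyses of how local structure shields the ³⁰⁶VQIVYK³¹¹
amyloid motif of tau.

Tau aggregation in tauopathies is driven by the PHF6 hexapeptide VQIVYK
(residues 306–311 in 2N4R numbering). In the soluble protein this motif is
thought to be sequestered inside a β-hairpin formed with the upstream
repeat-2 flanking sequence; disease mutations such as P301L/P301S, elevated
temperature, and 4R-specific flanking sequences destabilize that hairpin and
unleash aggregation. This package implements the downstream quantitative
analyses by which that model is tested:

- **`taushield.xlms`** — cross-linking mass-spectrometry (DSS d0/d12)
  contact-map analysis: validation filters on xQuest-style identifications
  (score > 25, −2.2 ≤ ppm ≤ +3.8, %TIC > 10, peptide length ≥ 6, ≥ 4
  fragment ions or ≥ 3 contiguous per peptide), 5-of-5 replicate consensus,
  sector classification (N-term 243–310 / C-term 311–380 / N–C, with an
  R2R3 flag for 275–305 × 306–336 inter-repeat contacts), and differential
  retention across temperature and genotype. Includes the DSS mass
  arithmetic (d12−d0 = 12.075321 Da, light shift C₈H₁₀O₂ = 138.068080 Da,
  hydrolyzed mono-link = 156.078644 Da) computed from atomic masses.
- **`taushield.kinetics`** — ThT aggregation time courses: blank
  subtraction, 2:1 signal-to-background gating, per-condition max
  normalization, and per-replicate fits of the four-parameter Boltzmann
  sigmoid `y(t) = F₀ + A / (1 + exp((t½ − t)/τ))` with 95% CIs on t½
  (asymptotic or residual bootstrap).
- **`taushield.chimera`** — combinatorial chimeras between the repeat-1
  (²⁶⁴ENLKHQPGGGK²⁷⁴) and repeat-2 (²⁹⁵DNIKHVPGGGS³⁰⁵) leading strands
  ahead of the VQIVYK core: the strands differ at 4 positions, giving a
  2⁴ = 16-member panel; substitution-count → kinetic-regime classification
  and a log₁₀(t½)-per-substitution delay-trend fit.
- **`taushield.geometry`** — CA-only conformational-ensemble analysis:
  Kabsch superposition, pairwise RMSD matrices, inter-repeat end-to-end
  distances (264–280, 295–311, 327–343, 359–375), an RMSD-to-canonical-
  hairpin collective variable, Boltzmann-inverted free-energy profiles
  F = −k_B·T·ln p with bootstrap CIs, basin/barrier analysis, and k-medoids
  clustering.
- **`taushield.fret`** — FRET flow-cytometry biosensor quantification:
  spillover compensation, negative-control-calibrated triangular FRET-vs-CFP
  gating with an optional false-FRET exclusion boundary, and the integrated
  FRET density (% positive × median FRET of positives).
- **`taushield.simulate`** — synthetic-data generators for all four
  instrument outputs with known ground truth (per-sector contact survival
  probabilities, injected t½, hairpin fractions, spill fractions and
  positive fractions), so that every stage is testable without downloads.

## Worked example

Fit the half-time of a noisy synthetic triplicate generated at the
aggregation speed of the R2R3-P301L peptide fragment:

```python
from taushield import simulate as sim, kinetics as kin

spec = sim.KineticsSpec(t_half=7.2, tau_slope=0.6, baseline=40.0,
                        amplitude=800.0, noise_sd=8.0, duration=96.0,
                        n_replicates=3, condition="R2R3-P301L", seed=7)
traces, blanks = sim.gen_tht_traces(spec)
fits = [kin.fit_sigmoid(kin.subtract_blank(tr, blanks)) for tr in traces
        if kin.passes_signal_gate(tr, blanks)]
for f in fits:
    print(f"{f.condition} {f.replicate}: t1/2 = {f.t_half:.2f} h "
          f"(95% CI {f.ci95_t_half[0]:.2f}-{f.ci95_t_half[1]:.2f})")
s = kin.summarize_condition(fits)
print(f"condition mean t1/2 = {s.mean_t_half:.2f} h, replicate SD = {s.sd_t_half:.3f}")
```

prints

```
R2R3-P301L rep1: t1/2 = 7.19 h (95% CI 7.18-7.20)
R2R3-P301L rep2: t1/2 = 7.19 h (95% CI 7.17-7.20)
R2R3-P301L rep3: t1/2 = 7.20 h (95% CI 7.19-7.21)
condition mean t1/2 = 7.19 h, replicate SD = 0.007
```

— the injected 7.2 h half-time is recovered per replicate with tight
asymptotic CIs, and the replicate scatter (SD 0.007 h) reflects only the
injected 1% measurement noise.

Every module is also reachable from the `taushield` command line, e.g.

```bash
taushield simulate xlms --seed 3 --out sim/
taushield xlms consensus --in sim/crosslinks.tsv --out sim/consensus.tsv
taushield xlms sectors --in sim/consensus.tsv --out sim/sectors.tsv
taushield chimera enumerate --out panel.fasta
taushield fret quantify --in events.csv --out seeding.tsv
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data generators and
their defaults, numerical choices, and known limitations.
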