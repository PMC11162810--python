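# Methods

## Scope and model

`dusmap` analyses dihydrouridine (D) in tRNA through three independent
read-outs — MALDI mass mapping of digest fragments, aniline-cleavage
read-start sequencing, and steady-state flavoenzyme kinetics — and attributes
each modified site to one or both of two dihydrouridine synthase paralogs
(B1, B2) from a four-strain knockout panel (WT, ΔB1, ΔB2, ΔB1ΔB2).

The underlying biological model is a site served independently by a set of
enzymes, each with an efficiency e ∈ (0, 1]: the modified fraction
(stoichiometry) of the site in a given strain is

    p = 1 − Π over present enzymes (1 − e),

so deleting one enzyme of a redundant pair leaves the other's efficiency as
the residual stoichiometry, and the double deletion abolishes the signal.
This is the quantity both read-outs estimate: as the fragment-pair intensity
ratio f = I(mod)/(I(mod)+I(unmod)) in MALDI, and as the stop ratio
(counts/coverage) in sequencing.

## Position model

tRNA residues carry canonical-style labels (number plus optional insertion
letter: 17, 20, 20a, 20b, 47…) ordered by number then suffix, with the bare
number before any lettered insertion. No automatic canonical alignment is
performed: labels are supplied explicitly in a sidecar TSV or default to
1..n. All algorithms run on 0-based indices; labels are I/O only. This keeps
insertion-letter arithmetic out of the numerical code and reflects that
canonical numbering is an annotation convention, not a computable property
of a bare sequence.

## Digestion

RNase T1 cleaves 3′ of guanosine and RNase A 3′ of pyrimidines, leaving
3′-phosphate / 5′-OH products (linear phosphate by default; the 2′,3′-cyclic
intermediate is representable but off). Two modification-specific rules
matter and are configurable per `CleavageRule`:

* base-methylated G (m⁷G) remains a T1 substrate — its variable-loop
  neighbour fragment would otherwise never be released;
* D is treated as an RNase A substrate, as the observed D-terminal fragments
  (GGD, GGAD) require; whether cleavage after D is quantitative is not
  settled, hence the configurable rule;
* 2′-O-methylated residues (Um, Cm, Gm, Am) resist both enzymes because the
  transesterification needs the 2′-OH.

With k missed cleavages every union of ≤ k+1 adjacent complete-digest
fragments is also emitted; the complete digest always partitions the parent.
The whole-molecule 5′ terminus defaults to 5′-phosphate (mature tRNA); the
first fragment inherits it, everything downstream is 5′-OH.

## Masses

Monoisotopic element masses are hard-coded CODATA/IUPAC values at 5 decimals
(average masses from standard atomic weights); nucleotide residues are priced
as nucleoside-3′-monophosphates, fragments as Σ residues − (n−1)·H₂O with
terminal corrections (−HPO₃ for 3′-OH, −H₂O for cyclic phosphate, +HPO₃ for
5′-P) and the adduct (±1.00728 for [M±H]). The MALDI reporting convention is
singly protonated, monoisotopic, nominal-integer rounding (half away from
zero), matching integer peak labels on linear-mode spectra of short
oligonucleotides. Modification codes follow MODOMICS short names; the table
(code → parent base, mass deltas, cleavage flags) is user-extensible via TSV.
D adds +2.01565 Da to U.

## Diagnostic selection and the attribution grid

A site is monitorable when some digest fragment contains it and no other
candidate site, and neither member of its modified/unmodified mass pair lies
within the matching tolerance (default 0.5 Da, the realistic scale for
linear-mode MALDI-TOF of trinucleotides) of any other digest fragment mass.
The smallest such fragment is selected; sites without one are reported
unmonitorable rather than guessed at.

Peak matching sums intensity within tolerance of each pair member, with a
nearest-target rule when one peak could serve several diagnostics.
Intensities are relative within one spectrum only — MALDI intensities are
not quantitative across spots — so nothing is normalized across strains
beyond the within-spectrum fraction f.

Call thresholds (declared, not derivable from qualitative "absent"/
"decreased" statements): a site is *undetected* when the summed pair
intensity is below 5% of the spectrum's median peak intensity; *modified*
when f ≥ 0.8; *unmodified* when f ≤ 0.1; *reduced* in between. The decision
grid applies, in order: WT unmodified → `none`; double mutant still modified
→ `inconsistent` (contamination flag); detected in one single knockout but
unmodified in the other → `B1_only`/`B2_only`; detected in both singles and
lost in the double → `redundant`, with a preference suffix when the two
single-knockout fractions differ by at least 0.3 (the deeper drop names the
larger contributor). The grid is a pure function of the four states — site
order and tRNA identity cannot influence it.

## Cleavage-sequencing scores

Alkaline ring opening plus aniline scission leaves a 5′-phosphate on the
residue 3′ of the modified base, so a read start at position i+1 reports
residue i. This N+1 offset is undone inside the scoring functions; all
outputs are residue-coordinate.

* **NormCount** = attributed count / max(median of the attributed counts of
  the 10 nearest flanking positions, 1). "Surrounding 10 nucleotides" is
  read as 5 per side, excluding the scored position, truncated at molecule
  ends; the unit floor avoids division by zero on dead background. The score
  is scale-free (invariant to multiplying all counts by a constant while
  above the floor) but deliberately *not* linear in modification level — it
  trades linearity for sensitivity at low stoichiometry.
* **Stop ratio** = attributed counts / coverage at the attributed read
  start ∈ [0, 1]; zero coverage yields an explicit undetected marker, never
  a silent 0. It is the stoichiometry proxy used for heatmaps and the
  sequencing-side attribution, which feeds the same thresholds and decision
  grid as the MALDI side.

Site calling uses a NormCount threshold of 5.0 by default (exposed in the
CLI); no published cut-off exists, and the chosen value sits far above the
self-normalized background of 1 while well below the ≥ 60 scores typical of
spiked sites at the default synthetic settings. High scores at non-U
residues (the m⁷G/m³C/ho⁵C co-detection channel) are reported separately,
never suppressed and never called as D. Called D sites with stop ratio < 1
are flagged sub-stoichiometric. Deconvolving a variable-loop D from an
adjacent strong m⁷G signal is out of scope — the interference is intrinsic
to the chemistry.

## Kinetics

NAD(P)H oxidase rates are fitted to v = k_cat·[E]·[S]/(K_M+[S]) by bounded
nonlinear least squares with deterministic initial guesses (V_max⁰ = max
rate, K_M⁰ = median [S]) and residuals normalized to the observed rate scale
so convergence is independent of the absolute rate magnitude (turnovers here
span 0.013–0.7 s⁻¹). At least 5 distinct concentrations are required, and a
design whose concentrations all sit far above the fitted K_M (or whose K_M
standard error exceeds the estimate) is rejected as unidentifiable rather
than reported. Efficiencies k_cat/K_M (µM⁻¹ s⁻¹) carry first-order
propagated errors. Substrate preference uses the efficiency fold ratio with
a 1.5-fold indifference band: below it the enzyme is reported as not
discriminating between NADH and NADPH.

Rates may also be derived from A340 slopes using ε(NAD(P)H, 340 nm) =
6220 M⁻¹ cm⁻¹ at 1 cm path — constants declared here, not package inputs.

Cooperative tRNA binding monitored through FMN fluorescence is fitted with
the Hill isotherm ΔF = A·Sⁿ/(K½ⁿ + Sⁿ), n ∈ [0.05, 10]; n = 1 reduces to the
hyperbola. Relative D content across strains is (D/A)_sample /
(D/A)_reference × 100 with adenosine-UV normalization, invariant to common
rescaling of the raw signals.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (parameters, seed) and produce exactly
the TSV/FASTA dialects the analysis reads.

* **Substrates**: ~76-nt sequences in which each requested canonical site is
  a U embedded in a G-flanked context whose prefix composition is unique
  within the molecule, so T1 digestion yields one small, collision-free
  diagnostic fragment per site. Filler positions use A/C only (no stray
  candidate U's, no extra cuts), ending in the universal CCA. Adjacent
  candidate sites (16/17, 20/20a/20b) cannot be monitored separately by
  digestion, so each tRNA receives one site per adjacency cluster. Default
  redundancy structure: 17 and 47 by B1 alone, 20/20a by both enzymes.
* **Spectra**: per purified tRNA and strain; each fragment contributes a
  peak (pair) with the genotype-dependent stoichiometry split, Gaussian m/z
  jitter (sd 0.05 Da) and log-normal intensity noise (CV 0.2).
* **Cleavage profiles**: Poisson(5) background read starts everywhere,
  plus Binomial(coverage = 1000, stoichiometry) events at the N+1 read start
  of each modified site — the offset is built in so scoring must undo it.
* **Kinetics**: exact Michaelis–Menten curves with multiplicative Gaussian
  noise.

Enzyme efficiencies default to Uniform(0.3, 0.9): in-cell dihydrouridine is
sub-stoichiometric, and this range exercises all grid outcomes including
near-margin preference calls. Noise defaults are declared values, not
measured ones.

What the generator does **not** emulate — and hence what green tests do not
demonstrate about real data: realistic base composition and secondary
structure; other modifications co-occurring on the same fragments; MALDI
isotope envelopes, in-source decay and metal adducts; coverage roll-off and
ligation bias in sequencing libraries; cross-spot intensity variation beyond
a single log-normal factor. The benchmark numbers (100% attribution at zero
noise, ≥ 95% at default noise over ~200 sites, site-calling sensitivity
≥ 0.95 at FDR ≤ 0.05) are properties of this generative model.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design: ~200
synthetic sites (67 tRNAs) for the attribution and site-calling benchmarks,
1000 random sequences ≤ 30 nt against the brute-force digestion oracle, 100
seeded simulations for kinetic parameter recovery at 2% noise, and a
6-tRNA panel simulated twice for the byte-identical determinism check.
Ties and degenerate inputs are resolved explicitly: nominal rounding is half
away from zero; equal-length diagnostic candidates are taken in digest
order; the preference margin uses ≥; empty fragments, zero-coverage
positions, saturating kinetic designs and missing panel strains raise typed
errors instead of returning defaults.

## Known limitations

* The attribution grid is threshold-based, not probabilistic: no confidence
  is attached to a call, and values straddling a threshold flip the call
  rather than widen an interval.
* Fragment uniqueness is judged on masses within one digest of one tRNA;
  spectra of co-purified tRNA mixtures are not deconvolved (the CLI treats a
  peak table with a `trna_id` column as one spectrum per purified species).
* NormCount's background median assumes most flanking positions are
  unmodified; clusters of modified residues within a window bias scores
  downward.
* The Hill and Michaelis–Menten fits report asymptotic standard errors; no
  bootstrap or profile likelihood is provided.
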