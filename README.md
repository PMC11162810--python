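# dusmap

Desk-side analysis toolkit for mapping and quantifying **dihydrouridine (D)**
in tRNA. Dihydrouridine — uridine with a saturated C5–C6 bond (+2 H,
+2.016 Da) — is installed by FMN-dependent dihydrouridine synthases (Dus).
In Gram-positive bacteria such as *Bacillus subtilis* two DusB paralogs (here
"B1" and "B2") share overlapping site specificity, so working out *which
enzyme modifies which site* requires combining several read-outs across a
four-strain knockout panel (wild type, ΔB1, ΔB2, ΔB1ΔB2). `dusmap`
implements those read-outs as a reusable, tested pipeline:

1. **In-silico digestion** (`dusmap.digestion`) — RNase T1 (cuts 3′ of G)
   and RNase A (cuts 3′ of pyrimidines, including D) digestion of
   modification-annotated tRNAs into 3′-phosphate fragments, with missed
   cleavages and modification-dependent resistance (2′-*O*-methyl blocks
   both enzymes).
2. **Oligonucleotide masses** (`dusmap.masses`) — monoisotopic/average
   masses of modified fragments: Σ nucleoside-3′-monophosphates − (n−1)·H₂O
   plus terminal and adduct corrections. A D-containing fragment sits
   exactly 2 nominal Da above its U counterpart ([M+H]⁺, positive-mode
   MALDI), which is the diagnostic signal.
3. **Knockout-panel attribution** (`dusmap.maldi`) — per site, the smallest
   collision-free digest fragment is monitored; the modified fraction
   f = I(mod)/(I(mod)+I(unmod)) per strain feeds a deterministic decision
   grid: `B1_only`, `B2_only`, `redundant` (optionally with a preference
   suffix), `none` or `inconsistent`.
4. **Aniline-cleavage sequencing scores** (`dusmap.cleavage`) — per-position
   5′-P read-start counts are scored with *NormCount* (signal over the
   median background of the surrounding 10 nt) and the *stop ratio*
   (counts/coverage, a stoichiometry proxy), with the N+1 cleavage offset
   handled internally; co-detected non-U signals (e.g. m⁷G) are reported in
   a separate channel.
5. **Enzyme kinetics** (`dusmap.kinetics`) — Michaelis–Menten fits of
   NAD(P)H oxidase rates (v = k_cat·[E]·[S]/(K_M+[S])), catalytic-efficiency
   comparison with a 1.5-fold indifference band, Hill fits of cooperative
   tRNA-binding isotherms, and relative D content normalized to the
   adenosine UV signal.
6. **Synthetic data** (`dusmap.simulate`) — seeded generators for every
   input above with ground truth attached, so the whole pipeline is testable
   without any sequencing or spectrometry data.

## Worked example

```python
import numpy as np
from dusmap import (AnnotatedTRNA, select_diagnostics, attribute_panel, STRAINS)
from dusmap.simulate import gen_trna_set, gen_maldi_panel, NoiseConfig

# A substrate carrying two D sites in RNase T1 diagnostic contexts
trna = AnnotatedTRNA.from_sequence(
    "tRNA-Phe-like", "AAGGUUGUAGAACCA", modifications_at={6: "D", 8: "D"})
for d in select_diagnostics(trna, "RNaseT1", ["6", "8"])[0]:
    print(f"site {d.site}: fragment {d.fragment.display():8s} "
          f"m/z {d.mz_modified:.2f} / {d.mz_unmodified:.2f}")

# Synthetic four-strain knockout panel -> enzyme attribution
trnas, truth = gen_trna_set(3, seed=42)
noise, rng = NoiseConfig(seed=42), np.random.default_rng(42)
for t in trnas:
    sites = [r.label for r in t.residues if r.modification == "D"]
    dg, _ = select_diagnostics(t, "RNaseT1", sites)
    peaks = {g: gen_maldi_panel(t, truth, g, noise, rng=rng) for g in STRAINS}
    for panel in attribute_panel(peaks, dg):
        fs = " ".join(f"{g}={panel.fraction(g):.2f}" for g in STRAINS)
        print(f"{t.id} site {panel.site}: {fs} -> {panel.attribution}")
```

prints

```
site 6: fragment U[D]G    m/z 978.13 / 976.12
site 8: fragment [D]AG    m/z 1001.16 / 999.14
syn-tRNA-001 site 17: WT=0.67 dB1=0.00 dB2=0.68 dB1dB2=0.00 -> B1_only
syn-tRNA-001 site 20: WT=0.87 dB1=0.62 dB2=0.68 dB1dB2=0.00 -> redundant
syn-tRNA-001 site 47: WT=0.54 dB1=0.00 dB2=0.64 dB1dB2=0.00 -> B1_only
syn-tRNA-002 site 17: WT=0.59 dB1=0.00 dB2=0.63 dB1dB2=0.00 -> B1_only
syn-tRNA-002 site 20a: WT=0.94 dB1=0.84 dB2=0.34 dB1dB2=0.00 -> redundant_B2_preferred
...
```

The U-D-G trinucleotide is observed at nominal m/z 978 and its unmodified
U-U-G counterpart at 976 — losing the modification shifts the peak −2 Da.
A site whose modified fraction collapses only in the ΔB1 strain is called
`B1_only`; a site retained in both single knockouts but lost in the double
knockout is served redundantly, with the preference suffix naming the enzyme
whose deletion depressed the modified fraction more.

## Command line

Each verb is a thin wrapper over one module and writes TSV plus a JSON
manifest (same seed + config ⇒ byte-identical outputs):

```sh
dusmap simulate --n-trnas 10 --seed 1 --out sim/
dusmap attribute --fasta sim/trnas.fasta --modifications sim/modifications.tsv \
    --labels sim/labels.tsv \
    --peaks WT sim/peaks_WT.tsv --peaks dB1 sim/peaks_dB1.tsv \
    --peaks dB2 sim/peaks_dB2.tsv --peaks dB1dB2 sim/peaks_dB1dB2.tsv \
    --out attr/
dusmap alkascore --counts counts.tsv --fasta sim/trnas.fasta \
    --modifications sim/modifications.tsv --labels sim/labels.tsv --out scores/
dusmap kinetics --rates rates.tsv --enzyme-conc 0.01 --out kin/
dusmap report --maldi attr/attribution.tsv --out report/
```

Other verbs: `digest`, `mass`, `diagnose`.

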