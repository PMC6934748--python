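# meltdiag

In-silico design and interpretation of **short-amplicon high-resolution
melting (SA-HRMA)** assays for species diagnosis from DNA mini-barcodes.

Morphologically cryptic, sympatric species — the motivating case is a pair of
*Prokelisia*-like saltmarsh planthoppers whose males are hard to tell apart
and whose females and juveniles cannot be identified at all — can often be
separated by a handful of fixed nucleotide differences in a short stretch of
the COI barcode. When those differences change the G·C content of a small
(≲100 bp) PCR product, the two species' amplicons denature at measurably
different temperatures, and a closed-tube melt analysis identifies every
specimen in minutes for cents per reaction. `meltdiag` implements the entire
computational side of building such an assay:

1. **Site taxonomy** — classify each column of a species-labelled alignment
   as fixed diagnostic (species-disjoint states), shared polymorphic
   (plesiomorphic), or monomorphic; annotate transition/transversion, codon
   position and synonymy; summarize divergence and build the haplotype
   minimum spanning network.
2. **Thermodynamics** — unified nearest-neighbor ΔH/ΔS summation with
   entropic salt correction; for a non-self-complementary duplex at total
   strand concentration *C*<sub>T</sub>,

   *T*<sub>m</sub> = ΔH·1000 / (ΔS′ + *R* ln(*C*<sub>T</sub>/4)),

   plus the two-state equilibrium helicity curve θ(T) and a single additive
   instrument-calibration offset.
3. **Assay design** — enumerate 40–106 bp amplicon windows containing fixed
   sites, generate primer pairs under standard rules (length 16–25 nt, Tm
   band, GC fraction, homopolymer runs, no polymorphic 3′ terminus), and rank
   assays by the **minimum between-species ΔTm** over all haplotype pairs.
   In-silico PCR extracts the product a pair would amplify.
4. **Melt curves** — simulate instrument signals (two-state helicity ×
   baselines + jitter + noise), normalize, differentiate (Savitzky–Golay),
   call −dF/dT peaks, assign species by nearest reference peak with tolerance
   and margin rules, and emit a throughput report (failed / ambiguous /
   assigned / morphology-discordant, with half-up rounded percentages).
5. **Synthetic data** — deterministic generators for mini-barcode alignments
   with configurable fixed/shared site structure and for high-throughput
   specimen cohorts, so the full pipeline is testable without any sequence
   download.

## Worked example

```python
from meltdiag import (BarcodeSpec, classify_sites, design_assays,
                      make_minibarcode_alignment)

aln = make_minibarcode_alignment(BarcodeSpec(seed=1))   # 65 specimens, 60 bp
sites = classify_sites(aln)
ranked = design_assays(aln, require_primer_rules=False)
top = ranked[0]
print(top.pair.amplicon_start, top.pair.amplicon_end,
      round(top.min_between_species_dtm, 3))
```

prints

```
7 52 4.046
```

— the best amplicon window spans columns 7–52 and separates the worst
inter-species haplotype pair by a predicted 4.05 °C, far above the ~0.5 °C a
modern melter resolves. On the same fixture the site report finds exactly 8
polymorphic columns (4 fixed diagnostic, 4 shared), all transitions at third
codon positions, with a single non-synonymous ATA/ATG (Ile/Met) site; the
full-length 60 bp amplicon separates the species by ≥ 3.0 °C. The scripts in
`examples/` walk through assay design, cohort simulation + classification
(reproducing a 518-specimen throughput table with 1.7 % failures and 10.75 %
male morphology discordance), and the haplotype network; each prints the
numbers it computes and a line on what they mean.

A thin CLI mirrors the library: `meltdiag sites`, `meltdiag design`,
`meltdiag simulate`, `meltdiag classify`, `meltdiag report` (see
`meltdiag --help`).

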