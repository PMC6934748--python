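# Methods

## The diagnostic problem

Two sympatric species are to be told apart from a short, haploid,
protein-coding mini-barcode (mitochondrial COI is the canonical locus). A
column of the species-labelled alignment is **fixed diagnostic** when the two
species' observed character-state sets are disjoint (with `N` and `-`
treated as missing, never as states); it is **shared polymorphic**
(plesiomorphic, in the usage adopted here: state-sharing between species,
with no outgroup polarity implied) when some state occurs in both species.
Only fixed sites carry diagnostic signal; shared sites produce within-species
melt variability. Synonymy of a polymorphic site is decided per codon
background: the site's observed states are substituted into every observed
codon at that position, and the site is synonymous iff no background changes
its amino acid. The default genetic code is the standard table (1): an
ATA↔ATG third-position transition is then Ile↔Met, i.e. non-synonymous,
which is the reading the package's fixtures encode. Under the invertebrate
mitochondrial code (table 5, selectable) the same transition is silent — a
warning is emitted because the two codes disagree on exactly this case.

Coordinates are 0-based half-open everywhere; codon positions are reported
1/2/3.

## Thermodynamic model

Duplex ΔH/ΔS are unified nearest-neighbor sums: ten Watson–Crick doublet
parameters plus terminal A·T (+2.3 kcal/mol, +4.1 cal/mol·K) and G·C
(+0.1, −2.8) initiation terms, at the 1 M NaCl reference state. Entropy is
salt-corrected by 0.368·(N−1)·ln[Na⁺] cal/(mol·K); free Mg²⁺ is folded into
a monovalent equivalent as [Na⁺]ₑq = [mono] + 120·√([Mg²⁺] mM) (mM scale).
The melting temperature of a non-self-complementary duplex with equal
strands (a PCR product) is

    Tm = ΔH·1000 / (ΔS' + R·ln(CT/4))        [Kelvin]

Defaults: 50 mM monovalent, 2 mM free Mg²⁺, CT = 0.25 µM. These place a
~35 %-GC 60-mer near 75 °C, the right regime for short-amplicon HRM.

Melting is assumed two-state (all-or-none), justified for single-domain
amplicons up to ~110 bp; multi-domain statistical-mechanics melting is out of
scope. The equilibrium duplex fraction solves a(1−θ)² = 2θ with
a = K·CT, computed in the cancellation-free form θ = a/(1+a+√(1+2a)), so
θ(Tm) = 0.5 exactly.

Absolute peak temperatures on a real instrument depend on the saturating dye
and optics, which are not modelled; a single additive
`calibration_offset_C`, set by `calibrate_offset(predicted, observed)`
against any observed peak, maps the prediction onto the instrument scale.
Only *differences* in Tm are treated as model-testable; ΔTm between two
sequences is invariant under the offset by construction.

## Assay design and ranking

Candidate amplicons are all windows of 40–106 bp (defaults) containing at
least one fixed site. Primer pairs are read off the majority consensus with
standard short-amplicon rules: length 16–25 nt, predicted primer Tm in
50–62 °C, GC fraction 0.30–0.70, no single-base run longer than 4, and a 3′
terminus never on a polymorphic column (a variant 3′ base would amplify
allele-specifically). Windows whose terminal 18 bp footprints overlap
polymorphic sites are flagged but not discarded.

Amplicon Tm is computed on the full excised product, primer footprints
included. The ranking statistic is the **minimum between-species |ΔTm| over
all inter-species haplotype pairs** — the bound on how well the worst pair
resolves — sorted descending, with amplicon length (shorter first) and
start position as tie-breaks. Real amplification efficiency cannot be
predicted from sequence alone; primer-rule compliance stands in for it as a
hard filter, and `design_assays(require_primer_rules=False)` scores every
window with default consensus footprints when rule-conforming primers are
not the question being asked.

In-silico PCR locates the forward primer and the reverse complement of the
reverse primer with a mismatch budget (default 2) but an exact-match
requirement at the 3′-terminal base, and demands a unique product.

## Melt-curve model and processing

The simulated signal is

    F(T) = amplitude · θ(T + δ − jitter) · (1 + pre_slope·(T−T0))
           + post_level + post_slope·(T−T0) + ε

with per-specimen jitter ~ N(0, sd_tm) emulating well-to-well variation and
ε ~ N(0, sd_fluor) fluorescence noise. One modelling convention deserves
note: the bimolecular two-state transition is asymmetric — its −dθ/dT
maximum falls where K·CT = 1+√2, about 0.25 °C above the θ = 0.5 point for
a 60-mer (ΔH ≈ −450 kcal/mol). Because melters report *peak* temperatures
and the classifier consumes peaks, curves are emitted in peak-position
convention: the fixed shift δ, located numerically on the noiseless signal,
places the −dF/dT maximum exactly at the duplex's calibrated Tm.

Processing follows instrument software: linear baselines fitted on pre-melt
(66–68 °C) and post-melt (83–85 °C) windows normalize the curve to [0, 1]
(clipped to [−0.05, 1.05]; affine-invariant by construction); the derivative
is a Savitzky–Golay first derivative (window 31 points = 1.55 °C, cubic) and
the peak is refined sub-grid by a least-squares parabola over the top
±0.5 °C. The wide window and the parabola-over-the-top estimator were chosen
over a 3-point interpolation because point-level noise otherwise both throws
spurious global maxima in the baselines and lets the argmax wander across
the flat peak top; with them the noiseless peak bias is below one grid step
(0.05 °C) for peaks in ~70–81 °C on the default 65–85 °C grid.

Species calling is nearest-reference with two thresholds: the peak must lie
within `tau_C` (default 0.75 °C) of a reference and the gap to the runner-up
reference must be at least `min_margin_C` (default 0.5 °C); otherwise the
curve is ambiguous. References closer than 2·tau are rejected as
non-diagnostic. Failure is detected twice: a raw pre-minus-post amplitude
below `min_amplitude` (default 0.1) before normalization, and a derivative
peak below `min_height` (default 0.05) after — real instruments flag failed
amplifications visually, so both thresholds are exposed in the config.

The throughput report counts failed, ambiguous and per-species assigned
calls, total and per sex, plus calls discordant with prior (morphology)
labels. Discordance is counted over specimens with a prior label and a
successful unambiguous call, while its percentage uses *all* prior-labelled
specimens of the group as denominator — so 30 discordant of 279 labelled
males is 10.75 % (10.8 % at one decimal; percentages are emitted half-up at
both precisions).

## What the synthetic data emulates — and what it does not

`make_minibarcode_alignment` reproduces the structural facts of a real
two-species mini-barcode rather than any literal sequence: an in-frame
backbone at ~35 % GC (COI-like; stop codons avoided), a configurable number
of fixed and shared sites, all transitions at third codon positions, exactly
one non-synonymous fixed site realized as ATA/ATG, G/C states at fixed sites
in the GC-biased species and A/T in the other, and three haplotypes per
species differing only at shared sites, with geometric (4:2:1) specimen
counts over 43 + 22 individuals by default. At shared sites the variant
state is G/C in the GC-biased (higher-melting) species and A/T in the other,
so within-species variability spreads *away* from the sister species — the
configuration under which plesiomorphies visibly perturb melt profiles
without eroding the fixed-site separation, which stays ≥ 1.7 °C on the
default fixture (≈ 3.0 °C for the full 60 bp amplicon, ≈ 4 °C for the best
sub-window).

`make_cohort` emulates a high-throughput plate: 518 specimens, 279 males
carrying prior morphology labels, exactly round(fail_rate·n) = 9
amplification failures drawn from males only (the emulated table reports
zero female failures), and exactly 30 male labels flipped — drawn from
non-failed males so every discordance is observable, and never touching the
true species used for simulation. By default specimens melt at their
species' reference peak (79.4 / 77.0 °C, ΔTm 2.4) plus jitter; setting
`reference_tm_C=None` draws per-haplotype Tms from a scored assay instead.
The species-level default is deliberate: with one reference peak per species
and tau = 0.75 °C, per-haplotype Tm spread (~0.5 °C) stacked on jitter tails
would occasionally exceed tau, and classifying haplotype-spread cohorts
robustly requires per-haplotype references, which the single-Tm-per-species
classifier contract does not carry.

Passing tests on these generators therefore demonstrate correctness of the
algorithms under controlled conditions — not performance on real chemistry:
sequencing error, indels, heteroplasmy, nuclear pseudogenes, heteroduplexes,
dye redistribution and multi-domain melting are all outside the model.

## Numerical and design choices

- Haplotype collapse orders by descending count, then sequence, then label;
  ties everywhere are broken deterministically, so ranking and networks are
  stable under input permutation.
- Hamming distances ignore positions where either sequence has `N` or `-`.
- The minimum spanning network runs Kruskal with union-find; within each
  weight class, every edge joining components *as of the class start* is
  retained, the first per component pair as a spanning edge and the rest as
  flagged alternatives. Spanning weight is provably minimal (verified by
  exhaustive enumeration in tests).
- Inter-species divergence is an unweighted mean over distinct haplotype
  pairs, not frequency-weighted.
- Consensus ties break to the lexicographically smallest base.
- Percentages round half-up at the printed precision via decimal arithmetic.
- All generators are pure functions of spec + seed (numpy `default_rng`).

## Problem sizes

Default test and acceptance runs use the 65-specimen / 60 bp fixture, full
window enumeration (~230 candidates), 518-curve cohorts on a 401-point grid
over ten seeds, and exhaustive oracles up to duplex length 6 and six-node
networks — sizes chosen so the whole suite completes in well under a minute
while still exercising every code path against an independent oracle.
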