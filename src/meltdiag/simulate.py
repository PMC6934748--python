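"""Deterministic synthetic data: mini-barcode alignments and specimen cohorts.

No public sequence accessions exist for the planthopper study system this
toolkit emulates, so every stage is exercised against generated data that
reproduces the *structure* of a real two-species COI mini-barcode:

* :func:`make_minibarcode_alignment` builds an in-frame 60 bp (by default)
  alignment with a configurable number of fixed diagnostic and shared
  (plesiomorphic) polymorphic sites — all transitions at third codon
  positions, exactly one of them non-synonymous (an ATA↔ATG Ile/Met codon) —
  expanded to three haplotypes per species with realistic specimen counts.
  G/C states at fixed sites go to the GC-biased (higher-melting) species. At
  shared sites the variant state is likewise G/C in the GC-biased species and
  A/T in the other, so within-species melt variability spreads *away* from
  the other species and does not erode the fixed-site separation.

* :func:`make_cohort` builds a high-throughput specimen cohort (melt curves +
  metadata) with exact numbers of amplification failures (male-only by
  default) and morphology-label discordances, for testing classification and
  reporting end to end.

All generators are pure functions of their spec (including its seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignedRecord, LabelledAlignment
from .curves import MeltCurve, MeltSimParams, simulate_melt_curve
from .design import AssayCandidate, PrimerPair, in_silico_pcr
from .errors import SpecError
from .thermo import ThermoConditions

# Codon prefixes whose third-position A<->G transition is synonymous under the
# standard code and never forms a stop codon.
_AG_SAFE_PREFIXES = ("CT", "GT", "CC", "GG", "TC", "AC", "CG", "GC", "CA", "GA", "AA", "AG")
# Third-position C<->T transitions are always synonymous under the standard
# code; these prefixes additionally avoid stops.
_CT_SAFE_PREFIXES = ("AT", "TG", "CA", "AA", "GA", "TT", "AG", "TA", "CT", "GT")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class BarcodeSpec:
    """Structure of the generated mini-barcode alignment."""

    length_bp: int = 60
    n_fixed_sites: int = 4
    n_shared_sites: int = 4
    haplotypes_per_species: int = 3
    species_labels: tuple[str, str] = ("marginata-like", "dolus-like")
    gc_bias_species: str | None = None  # defaults to species_labels[0]
    n_per_species: tuple[int, int] = (43, 22)
    backbone_gc: float = 0.35
    seed: int = 0

    @property
    def gc_species(self) -> str:
        return self.gc_bias_species or self.species_labels[0]

    def validate(self) -> None:
        if self.length_bp % 3 != 0:
            raise SpecError("length_bp must be a multiple of 3 (in-frame barcode)")
        if self.length_bp < 40:
            raise SpecError("length_bp must be >= 40")
        n_codons = self.length_bp // 3
        if self.n_fixed_sites + self.n_shared_sites > n_codons:
            raise SpecError(
                "n_fixed + n_shared exceeds the number of third codon positions"
            )
        if self.n_fixed_sites < 0 or self.n_shared_sites < 0:
            raise SpecError("site counts must be >= 0")
        if self.haplotypes_per_species < 1:
            raise SpecError("haplotypes_per_species must be >= 1")
        extra = self.haplotypes_per_species - 1
        if extra > 0:
            per_species = _split_shared(self.n_shared_sites)
            if min(per_species) < extra:
                raise SpecError(
                    "not enough shared sites to realize "
                    f"{self.haplotypes_per_species} haplotypes per species"
                )
        elif self.n_shared_sites > 0:
            raise SpecError(
                "shared sites require haplotypes_per_species >= 2 to be "
                "polymorphic"
            )
        if min(self.n_per_species) < self.haplotypes_per_species:
            raise SpecError("n_per_species must be >= haplotypes_per_species")
        if self.gc_bias_species not in (None, *self.species_labels):
            raise SpecError("gc_bias_species must be one of species_labels")


def _split_shared(n_shared: int) -> tuple[int, int]:
    """Shared sites alternate between the two species (A gets the extra one)."""
    return (math.ceil(n_shared / 2), n_shared // 2)


def _spread_indices(n_slots: int, n_pick: int) -> list[int]:
    """n_pick distinct indices spread evenly over range(n_slots)."""
    if n_pick == 0:
        return []
    if n_pick == 1:
        return [0]
    picks = sorted({int(round(x)) for x in np.linspace(0, n_slots - 1, n_pick)})
    free = iter(i for i in range(n_slots) if i not in picks)
    while len(picks) < n_pick:
        picks.append(next(free))
    return sorted(picks)


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    while True:
        codon = "".join(rng.choice(list("ACGT"), size=3, p=p))
        if codon not in _STOPS:
            return codon


def make_minibarcode_alignment(spec: BarcodeSpec = BarcodeSpec()) -> LabelledAlignment:
    """Generate a species-labelled mini-barcode alignment per ``spec``.

    Reproducible: the same spec (same seed) always yields the same alignment.
    The result is guaranteed to contain exactly ``n_fixed_sites`` fixed
    diagnostic and ``n_shared_sites`` shared polymorphic columns, all
    third-position transitions, with exactly one non-synonymous fixed site
    (ATA/ATG) when ``n_fixed_sites >= 1``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_codons = spec.length_bp // 3
    n_sites = spec.n_fixed_sites + spec.n_shared_sites
    sp_a, sp_b = spec.species_labels
    gc_sp = spec.gc_species

    # Site layout. The default 60 bp / 4+4 structure pins the non-synonymous
    # fixed site to the 9th nucleotide (codon 3) and interleaves shared sites
    # at polymorphic ordinals 1, 3, 5, 8 (1-based).
    if (spec.n_fixed_sites, spec.n_shared_sites) == (4, 4) and n_codons >= 20:
        site_codons = [0, 2, 5, 8, 11, 14, 16, 19]
        shared_ords = {0, 2, 4, 7}
    else:
        site_codons = _spread_indices(n_codons, n_sites)
        shared_ords = set(_spread_indices(n_sites, spec.n_shared_sites))
    fixed_ords = [o for o in range(n_sites) if o not in shared_ords]
    shared_ord_list = sorted(shared_ords)

    # codon prefix + per-role third-position states for every site
    codons: dict[int, str] = {}  # codon index -> prefix (first two bases)
    site_states: dict[int, dict] = {}  # ordinal -> description
    for rank, ordinal in enumerate(fixed_ords):
        codon_idx = site_codons[ordinal]
        if rank == 0:
            prefix, high, low = "AT", "G", "A"  # ATG (Met) vs ATA (Ile)
        else:
            if rng.random() < 0.5:
                prefix = str(rng.choice(_AG_SAFE_PREFIXES))
                high, low = "G", "A"
            else:
                prefix = str(rng.choice(_CT_SAFE_PREFIXES))
                high, low = "C", "T"
        codons[codon_idx] = prefix
        site_states[ordinal] = {
            "kind": "fixed",
            "codon": codon_idx,
            gc_sp: high,
            (sp_b if gc_sp == sp_a else sp_a): low,
        }
    for k, ordinal in enumerate(shared_ord_list):
        codon_idx = site_codons[ordinal]
        owner = spec.species_labels[k % 2]
        if rng.random() < 0.5:
            prefix = str(rng.choice(_AG_SAFE_PREFIXES))
            high, low = "G", "A"
        else:
            prefix = str(rng.choice(_CT_SAFE_PREFIXES))
            high, low = "C", "T"
        # variant spreads away from the other species' melting range
        backbone, variant = (low, high) if owner == gc_sp else (high, low)
        codons[codon_idx] = prefix
        site_states[ordinal] = {
            "kind": "shared",
            "codon": codon_idx,
            "owner": owner,
            "backbone": backbone,
            "variant": variant,
        }

    backbone_codons = [
        codons[i] + "N" if i in codons else _random_codon(rng, spec.backbone_gc)
        for i in range(n_codons)
    ]

    def species_base(sp: str) -> list[str]:
        seq = list("".join(backbone_codons))
        for info in site_states.values():
            pos = info["codon"] * 3 + 2
            if info["kind"] == "fixed":
                seq[pos] = info[sp]
            else:
                seq[pos] = info["backbone"]
        return seq

    shared_by_species = {
        sp: [
            site_states[o]
            for o in shared_ord_list
            if site_states[o]["owner"] == sp
        ]
        for sp in spec.species_labels
    }

    records = []
    for sp, n_sp in zip(spec.species_labels, spec.n_per_species):
        base = species_base(sp)
        hap_seqs = ["".join(base)]
        # distribute every owned shared site over the variant haplotypes
        # (round-robin) so each configured site is actually polymorphic
        n_variant_haps = spec.haplotypes_per_species - 1
        for k in range(n_variant_haps):
            variant = list(base)
            for j, info in enumerate(shared_by_species[sp]):
                if j % n_variant_haps == k:
                    variant[info["codon"] * 3 + 2] = info["variant"]
            hap_seqs.append("".join(variant))
        counts = _haplotype_counts(n_sp, len(hap_seqs))
        i = 0
        for seq, cnt in zip(hap_seqs, counts):
            for _ in range(cnt):
                i += 1
                records.append(AlignedRecord(f"{sp}_{i:03d}", sp, seq))
    return LabelledAlignment(tuple(records), frame_offset=0)


def _haplotype_counts(n: int, k: int) -> list[int]:
    """Split n specimens over k haplotypes with geometric 2^-i weights
    (largest-remainder rounding); every haplotype gets at least one."""
    weights = np.array([2.0 ** -i for i in range(k)])
    raw = n * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > n:
        counts[int(np.argmax(counts))] -= 1
    rema = raw - counts
    while counts.sum() < n:
        j = int(np.argmax(rema))
        counts[j] += 1
        rema[j] = -1
    return counts.tolist()


@dataclass(frozen=True)
class CohortSpec:
    """High-throughput cohort emulation: sizes, rates and noise.

    Defaults emulate a 518-specimen run: 279 males carrying prior morphology
    labels, 9 amplification failures (all male), 30 male labels flipped
    (morphological misidentification), species references 79.4 / 77.0 °C.
    """

    n_specimens: int = 518
    n_males: int = 279
    species_labels: tuple[str, str] = ("marginata-like", "dolus-like")
    #: P(specimen belongs to species_labels[0]); default 296/509
    p_species_a: float = 296 / 509
    fail_rate: float = 9 / 518
    fail_males_only: bool = True
    male_label_discordance_rate: float = 30 / 279
    #: species-level melting-peak references; set None to use an assay's
    #: per-haplotype predicted Tm instead
    reference_tm_C: tuple[float, float] | None = (79.4, 77.0)
    dh_kcal: float = -450.0  # transition sharpness of the simulated duplex
    sim: MeltSimParams = field(default_factory=MeltSimParams)
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.p_species_a <= 1:
            raise SpecError("p_species_a must be in [0, 1]")
        for r in (self.fail_rate, self.male_label_discordance_rate):
            if not 0 <= r <= 1:
                raise SpecError("rates must be in [0, 1]")
        if not 0 <= self.n_males <= self.n_specimens:
            raise SpecError("n_males must be within n_specimens")
        n_fail = round(self.fail_rate * self.n_specimens)
        if self.fail_males_only and n_fail > self.n_males:
            raise SpecError("more failures than males with fail_males_only")
        n_flip = round(self.male_label_discordance_rate * self.n_males)
        if n_flip + (n_fail if self.fail_males_only else 0) > self.n_males:
            raise SpecError("discordant + failed males exceed n_males")


def make_cohort(
    spec: CohortSpec = CohortSpec(),
    assay: AssayCandidate | None = None,
    cond: ThermoConditions = ThermoConditions(),
) -> tuple[list[MeltCurve], pd.DataFrame]:
    """Simulate melt curves and metadata for a specimen cohort.

    Exactly ``round(fail_rate · n)`` specimens fail (zero amplitude), drawn
    from males only by default; exactly ``round(discordance_rate · n_males)``
    male prior labels are flipped, drawn from non-failed males so every
    discordance is observable in a successful call. Label flips never change
    the species used for curve simulation. Specimen melting temperatures come
    from ``spec.reference_tm_C`` per species, or — when that is None — from
    the per-haplotype predicted Tm of ``assay``.

    Returns the curves and a metadata table with columns specimen_id, sex,
    prior_label, true_species, haplotype, amplified.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sp_a, sp_b = spec.species_labels
    n = spec.n_specimens

    if spec.reference_tm_C is None:
        if assay is None:
            raise SpecError("reference_tm_C is None but no assay was given")
        tms_by_species = {sp_a: [], sp_b: []}
        for (sp, idx), tm in assay.per_haplotype_tm.items():
            if sp in tms_by_species:
                tms_by_species[sp].append((f"h{idx}", tm))
        if not (tms_by_species[sp_a] and tms_by_species[sp_b]):
            raise SpecError("assay lacks per-haplotype Tm for both species")
    else:
        tms_by_species = {
            sp: [("h0", tm)] for sp, tm in zip(spec.species_labels, spec.reference_tm_C)
        }

    true_species = np.where(
        rng.random(n) < spec.p_species_a, sp_a, sp_b
    )
    sex = np.array(["male"] * spec.n_males + ["female"] * (n - spec.n_males))
    male_idx = np.arange(spec.n_males)

    n_fail = round(spec.fail_rate * n)
    fail_pool = male_idx if spec.fail_males_only else np.arange(n)
    failed = set(rng.choice(fail_pool, size=n_fail, replace=False).tolist()) if n_fail else set()

    n_flip = round(spec.male_label_discordance_rate * spec.n_males)
    flip_pool = np.array([i for i in male_idx if i not in failed])
    flipped = set(rng.choice(flip_pool, size=n_flip, replace=False).tolist()) if n_flip else set()

    other = {sp_a: sp_b, sp_b: sp_a}
    curves, meta = [], []
    for i in range(n):
        sid = f"sp{i + 1:04d}"
        sp = str(true_species[i])
        hap_name, tm = tms_by_species[sp][rng.integers(len(tms_by_species[sp]))]
        is_failed = i in failed
        params = replace(spec.sim, amplitude=0.0) if is_failed else spec.sim
        curves.append(
            simulate_melt_curve(spec.dh_kcal, tm, cond, params, rng, specimen_id=sid)
        )
        prior = None
        if sex[i] == "male":
            prior = other[sp] if i in flipped else sp
        meta.append(
            {
                "specimen_id": sid,
                "sex": str(sex[i]),
                "prior_label": prior,
                "true_species": sp,
                "haplotype": hap_name,
                "amplified": not is_failed,
            }
        )
    return curves, pd.DataFrame(meta)


def make_pcr_template(
    spec: BarcodeSpec,
    primer_pair: PrimerPair,
    flank_bp: int = 50,
) -> str:
    """Random template embedding exact sites for ``primer_pair`` such that
    in-silico PCR yields a unique product of exactly ``spec.length_bp``.

    flanks + forward site + interior + reverse-complement site + flanks; the
    interior length is ``length_bp`` minus both primer lengths.
    """
    if flank_bp < 0:
        raise SpecError("flank_bp must be >= 0")
    from .alignment import reverse_complement

    f, r = primer_pair.forward_seq, primer_pair.reverse_seq
    interior_len = spec.length_bp - len(f) - len(r)
    if interior_len < 0:
        raise SpecError("primers longer than the requested amplicon")
    rng = np.random.default_rng(spec.seed)
    p = [(1 - spec.backbone_gc) / 2, spec.backbone_gc / 2, spec.backbone_gc / 2, (1 - spec.backbone_gc) / 2]

    def draw(k: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=k, p=p)) if k else ""

    for _ in range(50):
        template = draw(flank_bp) + f + draw(interior_len) + reverse_complement(r) + draw(flank_bp)
        try:
            product = in_silico_pcr(template, primer_pair, max_mismatches=2)
        except Exception:
            continue
        if product is not None and len(product) == spec.length_bp:
            return template
    raise SpecError("could not build an unambiguous template; adjust spec")
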