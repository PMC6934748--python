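"""Mini-amplicon assay design and ranking by predicted melting separation.

Given a diagnosed two-species alignment, this module enumerates candidate
amplicon windows that contain fixed diagnostic sites, generates primer pairs
under standard short-amplicon rules (length, Tm band, GC fraction, homopolymer
runs, no polymorphic 3' terminus), predicts the per-haplotype amplicon Tm with
the nearest-neighbor model and ranks assays by the *minimum* between-species
Tm difference — the quantity that bounds how well the worst haplotype pair can
be resolved on a melter. An in-silico PCR utility extracts the amplicon a pair
would produce from an arbitrary template.

Amplicon Tm is computed on the full excised amplicon, primer footprints
included, since the diagnostic sites of a mini-barcode may fall anywhere in
the product.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alignment import (
    Haplotype,
    LabelledAlignment,
    majority_consensus,
    reverse_complement,
)
from .errors import AmbiguityError, DesignError, InputError
from .sites import SiteClassification, fixed_sites, polymorphic_sites
from .thermo import ThermoConditions, duplex_tm

DEFAULT_LENGTH_WINDOW = (40, 106)
DEFAULT_FOOTPRINT_BP = 18


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair and the amplicon it delimits.

    ``forward_seq`` is 5'→3' on the reference strand, ``reverse_seq`` 5'→3' on
    the complement; coordinates are 0-based half-open on the reference.
    """

    forward_seq: str
    reverse_seq: str
    amplicon_start: int
    amplicon_end: int

    def __post_init__(self):
        if self.amplicon_end <= self.amplicon_start:
            raise InputError("amplicon_end must exceed amplicon_start")
        if len(self.forward_seq) + len(self.reverse_seq) > self.amplicon_length:
            raise InputError("primer footprints exceed amplicon length")

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start

    @classmethod
    def from_window(
        cls,
        reference: str,
        start: int,
        end: int,
        fwd_len: int = DEFAULT_FOOTPRINT_BP,
        rev_len: int = DEFAULT_FOOTPRINT_BP,
    ) -> "PrimerPair":
        """Primer pair read directly off a reference sequence window."""
        return cls(
            forward_seq=reference[start : start + fwd_len],
            reverse_seq=reverse_complement(reference[end - rev_len : end]),
            amplicon_start=start,
            amplicon_end=end,
        )


@dataclass(frozen=True)
class AmpliconWindow:
    """Candidate amplicon region containing fixed diagnostic sites."""

    start: int
    end: int
    fixed_sites: tuple[int, ...]
    footprint_polymorphic: bool  # polymorphic site inside a terminal footprint

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrimerConstraints:
    """Primer-quality rules for short-amplicon HRM assays."""

    min_len: int = 16
    max_len: int = 25
    tm_range_C: tuple[float, float] = (50.0, 62.0)
    gc_range: tuple[float, float] = (0.3, 0.7)
    max_run: int = 4


@dataclass(frozen=True)
class AssayCandidate:
    """A scored assay: primer pair, per-haplotype Tm and its separation."""

    pair: PrimerPair
    diagnostic_sites_covered: tuple[int, ...]
    per_haplotype_tm: dict
    min_between_species_dtm: float

    @property
    def rank_score(self) -> float:
        return self.min_between_species_dtm


def find_candidate_amplicons(
    aln: LabelledAlignment,
    sites: Sequence[SiteClassification],
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
    footprint_bp: int = DEFAULT_FOOTPRINT_BP,
) -> list[AmpliconWindow]:
    """Enumerate amplicon windows within the length bounds that contain at
    least one fixed diagnostic site.

    Windows whose terminal primer-footprint regions overlap any polymorphic
    site are flagged (``footprint_polymorphic``) but kept: a flagged window
    can still be rescued by shifting primers, and the amplicon Tm separation
    is unaffected.
    """
    fixed = fixed_sites(sites)
    if not fixed:
        raise DesignError(
            "no fixed diagnostic site between the two species: "
            "a melting assay cannot separate them"
        )
    poly = set(polymorphic_sites(sites))
    min_len, max_len = length_window
    out = []
    for start in range(0, aln.length - min_len + 1):
        for length in range(min_len, min(max_len, aln.length - start) + 1):
            end = start + length
            covered = tuple(p for p in fixed if start <= p < end)
            if not covered:
                continue
            fp = set(range(start, min(start + footprint_bp, end))) | set(
                range(max(end - footprint_bp, start), end)
            )
            out.append(
                AmpliconWindow(
                    start=start,
                    end=end,
                    fixed_sites=covered,
                    footprint_polymorphic=bool(fp & poly),
                )
            )
    return out


def _has_long_run(seq: str, max_run: int) -> bool:
    return any(
        len(list(g)) > max_run for _, g in itertools.groupby(seq)
    )


def _gc_fraction(seq: str) -> float:
    return sum(1 for b in seq if b in "GC") / len(seq)


def generate_primer_pairs(
    aln: LabelledAlignment,
    window: tuple[int, int],
    constraints: PrimerConstraints = PrimerConstraints(),
    cond: ThermoConditions = ThermoConditions(),
    sites: Sequence[SiteClassification] | None = None,
) -> list[PrimerPair]:
    """Enumerate primer pairs whose outer ends coincide with ``window``.

    Primers are read off the majority consensus. Rules: length within bounds,
    NN-predicted Tm in the configured band, GC fraction in range, no
    single-base run longer than ``max_run``, and the 3'-terminal base must not
    sit on a polymorphic column (a variant 3' end would amplify allele-
    specifically). All forward x reverse combinations are returned.
    """
    from .sites import classify_sites  # local import to avoid cycle at import time

    start, end = window
    if not (0 <= start < end <= aln.length):
        raise InputError(f"window {window} outside alignment of length {aln.length}")
    if sites is None:
        sites = classify_sites(aln)
    poly = set(polymorphic_sites(sites))
    consensus = majority_consensus(r.sequence for r in aln.records)

    def _ok(seq: str) -> bool:
        if not set(seq) <= set("ACGT"):
            return False
        if _has_long_run(seq, constraints.max_run):
            return False
        if not (constraints.gc_range[0] <= _gc_fraction(seq) <= constraints.gc_range[1]):
            return False
        tm = duplex_tm(seq, cond)
        return constraints.tm_range_C[0] <= tm <= constraints.tm_range_C[1]

    forwards, reverses = [], []
    for length in range(constraints.min_len, constraints.max_len + 1):
        if length > end - start:
            break
        f_seq = consensus[start : start + length]
        if (start + length - 1) not in poly and _ok(f_seq):
            forwards.append(f_seq)
        r_seq = reverse_complement(consensus[end - length : end])
        if (end - length) not in poly and _ok(r_seq):
            reverses.append(r_seq)
    pairs = [
        PrimerPair(f, r, start, end)
        for f in forwards
        for r in reverses
        if len(f) + len(r) <= end - start
    ]
    if not pairs:
        warnings.warn(
            f"no primer pair satisfies the constraints in window {window}",
            stacklevel=2,
        )
    return pairs


def score_and_rank(
    candidates: Sequence[PrimerPair],
    haps: Sequence[Haplotype],
    cond: ThermoConditions = ThermoConditions(),
) -> list[AssayCandidate]:
    """Predict per-haplotype amplicon Tm and rank by between-species separation.

    For each candidate the amplicon is excised from every haplotype,
    its Tm predicted, and the minimum |ΔTm| over all inter-species haplotype
    pairs recorded. Sort order: min ΔTm descending, then amplicon length
    ascending, then start ascending — separation first, shorter products
    preferred among equals. Haplotypes whose amplicon contains N or a gap are
    skipped with a warning; candidates covering no fixed diagnostic site (or
    leaving a species without any scored haplotype) are dropped.
    """
    if not candidates:
        raise InputError("no candidate primer pairs to score")
    species = sorted({h.species_label for h in haps})
    if len(species) < 2:
        raise InputError("haplotypes must span two species")
    length = len(haps[0].sequence)
    seqs_by_species = {
        sp: [h.sequence for h in haps if h.species_label == sp] for sp in species
    }
    from .sites import _column_states  # shared column-state rule

    fixed_cols = [
        pos
        for pos in range(length)
        if (lambda sa, sb: sa and sb and not (sa & sb))(
            _column_states(seqs_by_species[species[0]], pos),
            _column_states(seqs_by_species[species[1]], pos),
        )
    ]

    scored = []
    for pair in candidates:
        covered = tuple(
            p for p in fixed_cols if pair.amplicon_start <= p < pair.amplicon_end
        )
        if not covered:
            continue
        per_tm: dict = {}
        for idx, hap in enumerate(haps):
            amp = hap.sequence[pair.amplicon_start : pair.amplicon_end]
            if not set(amp) <= set("ACGT"):
                warnings.warn(
                    f"haplotype {idx} skipped: amplicon contains N or gap",
                    stacklevel=2,
                )
                continue
            per_tm[(hap.species_label, idx)] = duplex_tm(amp, cond)
        dtms = [
            abs(per_tm[ka] - per_tm[kb])
            for ka in per_tm
            for kb in per_tm
            if ka[0] == species[0] and kb[0] == species[1]
        ]
        if not dtms:
            continue
        scored.append(
            AssayCandidate(
                pair=pair,
                diagnostic_sites_covered=covered,
                per_haplotype_tm=per_tm,
                min_between_species_dtm=min(dtms),
            )
        )
    scored.sort(
        key=lambda c: (
            -c.min_between_species_dtm,
            c.pair.amplicon_length,
            c.pair.amplicon_start,
        )
    )
    return scored


def _find_sites(template: str, probe: str, max_mismatches: int, exact_3prime_at: int) -> list[int]:
    """Start positions where ``probe`` matches ``template`` with at most
    ``max_mismatches`` mismatches; the probe position ``exact_3prime_at``
    (index into the probe) must match exactly."""
    hits = []
    n, m = len(template), len(probe)
    for pos in range(n - m + 1):
        seg = template[pos : pos + m]
        if seg[exact_3prime_at] != probe[exact_3prime_at]:
            continue
        mismatches = sum(1 for a, b in zip(seg, probe) if a != b)
        if mismatches <= max_mismatches:
            hits.append(pos)
    return hits


def in_silico_pcr(
    template: str, pair: PrimerPair, max_mismatches: int = 2
) -> str | None:
    """Amplicon the pair would produce from ``template``, or None.

    The forward primer and the reverse complement of the reverse primer are
    located on the template allowing up to ``max_mismatches`` each, with the
    3'-terminal base required to match exactly. Exactly one product must be
    formed; multiple products raise :class:`AmbiguityError` with the loci.
    """
    template = template.upper()
    f, r = pair.forward_seq, pair.reverse_seq
    if len(template) < len(f) + len(r):
        raise InputError("template shorter than combined primer length")
    r_site = reverse_complement(r)
    f_hits = _find_sites(template, f, max_mismatches, len(f) - 1)
    # the reverse primer's 3' end is the first base of its plus-strand site
    r_hits = _find_sites(template, r_site, max_mismatches, 0)
    products = [
        (q, p + len(r_site))
        for q in f_hits
        for p in r_hits
        if p >= q + len(f)
    ]
    if not products:
        return None
    if len(products) > 1:
        raise AmbiguityError(
            f"{len(products)} possible products", loci=products
        )
    q, e = products[0]
    return template[q:e]


def design_assays(
    aln: LabelledAlignment,
    species_pair: tuple[str, str] | None = None,
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
    constraints: PrimerConstraints = PrimerConstraints(),
    cond: ThermoConditions = ThermoConditions(),
    require_primer_rules: bool = True,
) -> list[AssayCandidate]:
    """Full pipeline: classify sites, enumerate windows, build primer pairs,
    score and rank.

    With ``require_primer_rules=False`` (or when no window yields a rule-
    conforming pair) every window is scored with default consensus footprints
    instead, so ranking by melting separation is always available even when
    strict primer chemistry rules cannot be met on a given template.
    """
    from .alignment import collapse_haplotypes
    from .sites import classify_sites

    sites = classify_sites(aln, species_pair)
    windows = find_candidate_amplicons(aln, sites, length_window)
    haps = collapse_haplotypes(aln)
    if species_pair is not None:
        haps = [h for h in haps if h.species_label in species_pair]

    pairs: list[PrimerPair] = []
    if require_primer_rules:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for w in windows:
                pairs.extend(
                    generate_primer_pairs(aln, (w.start, w.end), constraints, cond, sites)
                )
    if not pairs:
        consensus = majority_consensus(r.sequence for r in aln.records)
        for w in windows:
            fp = min(DEFAULT_FOOTPRINT_BP, w.length // 2)
            pairs.append(PrimerPair.from_window(consensus, w.start, w.end, fp, fp))
    return score_and_rank(pairs, haps, cond)


def candidates_to_frame(ranked: Sequence[AssayCandidate]):
    """Ranked assays as the candidate table (rank, primers, coords, ΔTm)."""
    import pandas as pd

    rows = []
    for rank, c in enumerate(ranked, start=1):
        rows.append(
            {
                "rank": rank,
                "fwd": c.pair.forward_seq,
                "rev": c.pair.reverse_seq,
                "start": c.pair.amplicon_start,
                "end": c.pair.amplicon_end,
                "length": c.pair.amplicon_length,
                "n_diag_sites": len(c.diagnostic_sites_covered),
                "min_dTm_C": round(c.min_between_species_dtm, 3),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["rank", "fwd", "rev", "start", "end", "length", "n_diag_sites", "min_dTm_C"],
    )
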