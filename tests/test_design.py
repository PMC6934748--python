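"""Amplicon window enumeration, primer rules, assay ranking, in-silico PCR."""

import warnings

import pytest

from meltdiag import (
    AlignedRecord,
    AmbiguityError,
    BarcodeSpec,
    DesignError,
    Haplotype,
    LabelledAlignment,
    PrimerConstraints,
    PrimerPair,
    classify_sites,
    collapse_haplotypes,
    design_assays,
    find_candidate_amplicons,
    generate_primer_pairs,
    in_silico_pcr,
    majority_consensus,
    make_pcr_template,
    reverse_complement,
    score_and_rank,
)
from meltdiag.sites import fixed_sites

# Primer pair printed for the winning planthopper assay: 18 nt forward,
# 22 nt reverse, 60 bp product.
FWD = "CCAGTACTTGCAGTTGCA"
REV = "GTTGATATAAGATTGGATCTCC"


@pytest.fixture(scope="module")
def printed_pair():
    return PrimerPair(FWD, REV, 0, 60)


@pytest.fixture(scope="module")
def printed_alignment():
    """Alignment whose consensus embeds the printed primer sites with two
    fixed interior differences between species."""
    interior_a = "TTAGCAGGTATCTCAAGCAT"  # 20 bp
    # two fixed transitions at interior positions 18, 19 (columns 36, 37)
    interior_b = interior_a[:18] + "GC"
    seq_a = FWD + interior_a + reverse_complement(REV)
    seq_b = FWD + interior_b + reverse_complement(REV)
    recs = tuple(
        [AlignedRecord(f"a{i}", "A", seq_a) for i in range(3)]
        + [AlignedRecord(f"b{i}", "B", seq_b) for i in range(3)]
    )
    return LabelledAlignment(recs)


class TestFindCandidateAmplicons:
    def test_includes_full_length_window(self, default_alignment, default_sites):
        wins = find_candidate_amplicons(default_alignment, default_sites)
        assert any(w.start == 0 and w.end == 60 for w in wins)

    def test_length_bounds_respected(self, default_alignment, default_sites):
        wins = find_candidate_amplicons(
            default_alignment, default_sites, length_window=(40, 106)
        )
        assert wins
        assert all(40 <= w.length <= 106 for w in wins)

    def test_every_window_covers_a_fixed_site(self, default_alignment, default_sites):
        fixed = set(fixed_sites(default_sites))
        for w in find_candidate_amplicons(default_alignment, default_sites):
            assert fixed & set(range(w.start, w.end))
            assert set(w.fixed_sites) <= fixed

    def test_no_fixed_sites_raises(self):
        recs = tuple(
            AlignedRecord(f"a{i}", "A", "ACGT" * 15) for i in range(2)
        ) + tuple(AlignedRecord(f"b{i}", "B", "ACGT" * 15) for i in range(2))
        aln = LabelledAlignment(recs)
        with pytest.raises(DesignError):
            find_candidate_amplicons(aln, classify_sites(aln))


class TestGeneratePrimerPairs:
    def test_printed_pair_among_candidates(self, printed_alignment):
        """With relaxed Tm constraints the printed primer pair is recovered
        from a template embedding its sites."""
        relaxed = PrimerConstraints(tm_range_C=(40.0, 75.0))
        pairs = generate_primer_pairs(printed_alignment, (0, 60), relaxed)
        assert (FWD, REV) in {(p.forward_seq, p.reverse_seq) for p in pairs}

    def test_homopolymer_run_excluded(self):
        seq = "AAAAA" + "GCGTACGTTGCACGTAGCTAGCAAGCTTAGCATCGAGGCATGCATCGATACGACA"
        assert len(seq) == 60
        seq_b = seq[:59] + "G"
        aln = LabelledAlignment(
            (
                AlignedRecord("a1", "A", seq),
                AlignedRecord("b1", "B", seq_b),
            )
        )
        relaxed = PrimerConstraints(tm_range_C=(30.0, 90.0), gc_range=(0.0, 1.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairs = generate_primer_pairs(aln, (0, 60), relaxed)
        assert all("AAAAA" not in p.forward_seq for p in pairs)

    def test_three_prime_on_polymorphic_column_excluded(self, printed_alignment):
        # interior differences sit at columns 36 and 37; a forward primer
        # ending there must be rejected
        relaxed = PrimerConstraints(
            min_len=16, max_len=40, tm_range_C=(30.0, 90.0), gc_range=(0.0, 1.0)
        )
        pairs = generate_primer_pairs(printed_alignment, (0, 60), relaxed)
        assert pairs
        for p in pairs:
            assert len(p.forward_seq) - 1 not in (36, 37)

    def test_no_conforming_primer_warns(self, printed_alignment):
        strict = PrimerConstraints(tm_range_C=(90.0, 95.0))
        with pytest.warns(UserWarning):
            pairs = generate_primer_pairs(printed_alignment, (0, 60), strict)
        assert pairs == []


class TestScoreAndRank:
    def test_separation_orders_candidates(self, cond):
        # window [0,40) carries 4 fixed differences, window [20,60) only 1
        base = "ATGCTTGCAGTCGATTACGACTGATCGATTGACTGCAGTTAGCTAGCATGCATTGCAAT"[:60]
        base = (base + "A" * 60)[:60]
        a = list(base)
        for pos in (5, 10, 15, 18, 45):
            a[pos] = "G"
        b = list(base)
        for pos in (5, 10, 15, 18, 45):
            b[pos] = "A"
        haps = [
            Haplotype("".join(a), "A", ("a1",)),
            Haplotype("".join(b), "B", ("b1",)),
        ]
        ref = "".join(a)
        pairs = [
            PrimerPair.from_window(ref, 0, 40, 10, 10),
            PrimerPair.from_window(ref, 20, 60, 10, 10),
        ]
        ranked = score_and_rank(pairs, haps, cond)
        assert ranked[0].pair.amplicon_start == 0
        assert (
            ranked[0].min_between_species_dtm > ranked[1].min_between_species_dtm
        )
        assert ranked[0].rank_score == ranked[0].min_between_species_dtm

    def test_fixture_top_assay_exceeds_min_separation(
        self, default_alignment, default_haplotypes, cond
    ):
        ranked = design_assays(default_alignment, require_primer_rules=False)
        assert ranked[0].min_between_species_dtm >= 1.7

    def test_within_species_variability_does_not_break_diagnosis(
        self, default_alignment, cond
    ):
        """Shared polymorphisms yield >=2 distinct within-species Tm values
        while the between-species separation stays diagnostic."""
        ranked = design_assays(default_alignment, require_primer_rules=False)
        full = [c for c in ranked if c.pair.amplicon_length == 60]
        assert full
        top = full[0]
        tms_a = sorted(
            tm for (sp, _), tm in top.per_haplotype_tm.items() if sp == "marginata-like"
        )
        assert len(set(round(t, 6) for t in tms_a)) >= 2
        assert top.min_between_species_dtm >= 1.7

    def test_ranking_stable_under_permutation(self, default_alignment, cond):
        ranked1 = design_assays(default_alignment, require_primer_rules=False)
        sites = classify_sites(default_alignment)
        wins = find_candidate_amplicons(default_alignment, sites)
        cons = majority_consensus(r.sequence for r in default_alignment.records)
        pairs = [
            PrimerPair.from_window(cons, w.start, w.end, min(18, w.length // 2), min(18, w.length // 2))
            for w in wins
        ]
        haps = collapse_haplotypes(default_alignment)
        r_fwd = score_and_rank(pairs, haps, cond)
        r_rev = score_and_rank(pairs[::-1], haps, cond)
        key = lambda c: (c.pair.amplicon_start, c.pair.amplicon_end)
        assert [key(c) for c in r_fwd] == [key(c) for c in r_rev]

    def test_covered_sites_subset_of_fixed(self, default_alignment, default_sites):
        ranked = design_assays(default_alignment, require_primer_rules=False)
        fixed = set(fixed_sites(default_sites))
        for cand in ranked:
            assert cand.diagnostic_sites_covered
            assert set(cand.diagnostic_sites_covered) <= fixed

    def test_gc_biased_species_always_melts_higher(self, default_alignment):
        ranked = design_assays(default_alignment, require_primer_rules=False)
        for cand in ranked:
            a = [tm for (sp, _), tm in cand.per_haplotype_tm.items() if sp == "marginata-like"]
            b = [tm for (sp, _), tm in cand.per_haplotype_tm.items() if sp == "dolus-like"]
            assert min(a) > max(b)


class TestInSilicoPCR:
    def test_printed_primers_yield_60bp_product(self, printed_pair):
        template = make_pcr_template(BarcodeSpec(seed=5), printed_pair, flank_bp=50)
        product = in_silico_pcr(template, printed_pair)
        assert product is not None and len(product) == 60
        assert product.startswith(FWD)
        assert product.endswith(reverse_complement(REV))

    def test_absent_primer_returns_none(self, printed_pair):
        assert in_silico_pcr("A" * 100, printed_pair) is None

    def test_duplicate_forward_site_ambiguous(self, printed_pair):
        inner = "T" * 20
        template = FWD + inner + FWD + inner + reverse_complement(REV)
        with pytest.raises(AmbiguityError) as exc:
            in_silico_pcr(template, printed_pair)
        assert len(exc.value.loci) == 2

    def test_mismatch_tolerance_requires_exact_3prime(self, printed_pair):
        template = make_pcr_template(BarcodeSpec(seed=5), printed_pair, flank_bp=20)
        # mutate the forward primer's 3'-terminal site base: no product
        idx = template.index(FWD) + len(FWD) - 1
        mutated = template[:idx] + ("T" if template[idx] != "T" else "G") + template[idx + 1 :]
        assert in_silico_pcr(mutated, printed_pair, max_mismatches=2) is None

    def test_short_template_rejected(self, printed_pair):
        from meltdiag import InputError

        with pytest.raises(InputError):
            in_silico_pcr("ACGT", printed_pair)
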