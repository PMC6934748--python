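"""Diagnostic-site taxonomy, divergence and haplotype networks.

A two-species mini-barcode alignment is diagnosed column by column: a *fixed
diagnostic* site has species-disjoint character-state sets (the basis of any
melting-based species call), while a *shared polymorphic* (plesiomorphic) site
carries a state observed in both species and contributes only within-species
melt variability. Substitutions are annotated as transitions or transversions
and, for protein-coding frames, as synonymous or not by translating every
observed codon variant on every observed codon background.

Haplotype relationships are summarized as a minimum spanning network over
Hamming distances: a Kruskal spanning structure in which equal-weight
alternative connections are retained, so reticulations between equally close
haplotypes are not hidden by an arbitrary tie-break.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import Haplotype, LabelledAlignment, translate_codons
from .errors import InputError

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

CATEGORIES = ("monomorphic", "fixed_diagnostic", "shared_polymorphic", "private_polymorphic")


@dataclass(frozen=True)
class SiteClassification:
    """Per-column diagnosis of a two-species alignment."""

    position: int
    states_by_species: Mapping[str, frozenset[str]]
    category: str
    substitution_kind: str  # transition | transversion | mixed | none
    codon_position: int  # 1 | 2 | 3
    synonymous: bool | None  # None when not applicable


@dataclass
class HaplotypeNetwork:
    """Minimum spanning network over haplotypes.

    ``edges`` holds ``(i, j, weight, alternative)`` tuples indexing ``nodes``;
    ``alternative`` marks equal-weight ties retained beyond a single spanning
    tree. ``tm_by_node`` can be filled with predicted melting temperatures.
    """

    nodes: list[Haplotype]
    edges: list[tuple[int, int, int, bool]]
    tm_by_node: dict[int, float] = field(default_factory=dict)

    @property
    def spanning_weight(self) -> int:
        return sum(w for _, _, w, alt in self.edges if not alt)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node_a": i,
                "node_b": j,
                "hamming": w,
                "alternative": alt,
                "species_a": self.nodes[i].species_label,
                "species_b": self.nodes[j].species_label,
            }
            for i, j, w, alt in self.edges
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "hamming", "alternative", "species_a", "species_b"])

    def to_dot(self) -> str:
        lines = ["graph msn {"]
        for idx, hap in enumerate(self.nodes):
            label = f"{hap.species_label} (n={hap.count})"
            if idx in self.tm_by_node:
                label += f"\\nTm {self.tm_by_node[idx]:.2f} C"
            # node area scales with specimen count
            lines.append(
                f'  h{idx} [label="{label}", width={0.4 + 0.1 * hap.count:.2f}];'
            )
        for i, j, w, alt in self.edges:
            style = ", style=dashed" if alt else ""
            lines.append(f'  h{i} -- h{j} [label="{w}"{style}];')
        lines.append("}")
        return "\n".join(lines)


def hamming(seq_a: str, seq_b: str) -> int:
    """Hamming distance ignoring positions where either sequence has N or -."""
    if len(seq_a) != len(seq_b):
        raise InputError("sequences of unequal length")
    missing = set("N-")
    return sum(
        1
        for a, b in zip(seq_a, seq_b)
        if a != b and a not in missing and b not in missing
    )


def _column_states(sequences: Iterable[str], position: int) -> frozenset[str]:
    return frozenset(s[position] for s in sequences if s[position] in "ACGT")


def _substitution_kind(states: frozenset[str]) -> str:
    if len(states) <= 1:
        return "none"
    if len(states) == 2:
        if states <= PURINES or states <= PYRIMIDINES:
            return "transition"
        return "transversion"
    return "mixed"


def _site_synonymous(
    sequences: Sequence[str],
    position: int,
    states: frozenset[str],
    frame_offset: int,
    code_table: int,
) -> bool | None:
    """Synonymy of one polymorphic column.

    The site's observed states are substituted into every observed codon
    background at that codon; the site is synonymous iff, on every background,
    all states translate to the same amino acid. Columns outside a complete
    codon return ``None``.
    """
    if position < frame_offset:
        return None
    codon_index = (position - frame_offset) // 3
    start = frame_offset + 3 * codon_index
    if start + 3 > len(sequences[0]):
        return None
    offset = position - start
    backgrounds = {
        s[start : start + 3]
        for s in sequences
        if set(s[start : start + 3]) <= set("ACGT")
    }
    if not backgrounds:
        return None
    for bg in backgrounds:
        aas = set()
        for state in states:
            codon = bg[:offset] + state + bg[offset + 1 :]
            aas.add(translate_codons(codon, 0, code_table))
        if len(aas) > 1:
            return False
    return True


def classify_sites(
    aln: LabelledAlignment,
    species_pair: tuple[str, str] | None = None,
    code_table: int = 1,
) -> list[SiteClassification]:
    """Classify every alignment column for a pair of species.

    ``species_pair`` defaults to the first two labels in the alignment. Under
    genetic code 5 (invertebrate mitochondrial) an ATA/ATG third-position
    transition is silent (both Met), unlike under the standard code — a
    warning is emitted because synonymy annotations then differ from the
    standard-code reading of the same alignment.
    """
    if species_pair is None:
        labels = aln.species_labels
        if len(labels) < 2:
            raise InputError("alignment has fewer than two species labels")
        species_pair = (labels[0], labels[1])
    if code_table == 5:
        warnings.warn(
            "genetic code table 5 selected: ATA encodes Met, so an ATA/ATG "
            "transition is synonymous under this code (non-synonymous under "
            "the standard code)",
            stacklevel=2,
        )
    sp_a, sp_b = species_pair
    seqs_a = aln.sequences_for(sp_a)
    seqs_b = aln.sequences_for(sp_b)
    all_seqs = list(seqs_a) + list(seqs_b)

    out: list[SiteClassification] = []
    for pos in range(aln.length):
        states_a = _column_states(seqs_a, pos)
        states_b = _column_states(seqs_b, pos)
        union = states_a | states_b
        if len(union) <= 1:
            category = "monomorphic"
        elif states_a and states_b:
            if states_a & states_b:
                category = "shared_polymorphic"
            else:
                category = "fixed_diagnostic"
        else:
            category = "private_polymorphic"
        synonymous = (
            _site_synonymous(all_seqs, pos, union, aln.frame_offset, code_table)
            if category != "monomorphic"
            else None
        )
        out.append(
            SiteClassification(
                position=pos,
                states_by_species={sp_a: states_a, sp_b: states_b},
                category=category,
                substitution_kind=_substitution_kind(union),
                codon_position=aln.codon_position(pos),
                synonymous=synonymous,
            )
        )
    return out


def fixed_sites(sites: Iterable[SiteClassification]) -> list[int]:
    return [s.position for s in sites if s.category == "fixed_diagnostic"]


def polymorphic_sites(sites: Iterable[SiteClassification]) -> list[int]:
    return [s.position for s in sites if s.category != "monomorphic"]


def sites_to_frame(sites: Iterable[SiteClassification]) -> pd.DataFrame:
    """Flatten classifications into the site-report table (one row/column)."""
    rows = []
    for s in sites:
        row = {
            "position": s.position,
            "codon_position": s.codon_position,
            "category": s.category,
            "substitution_kind": s.substitution_kind,
            "synonymous": s.synonymous,
        }
        for sp, states in s.states_by_species.items():
            row[f"states_{sp}"] = "/".join(sorted(states)) or "."
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_divergence(
    haps_a: Sequence[Haplotype], haps_b: Sequence[Haplotype]
) -> dict:
    """Inter-species divergence between two haplotype lists.

    Returns the |A| x |B| Hamming matrix, the unweighted mean over all
    inter-species haplotype pairs (haplotype-level, not frequency-weighted),
    and the count of fixed differences (columns with species-disjoint states).
    """
    if not haps_a or not haps_b:
        raise InputError("empty haplotype list")
    length = len(haps_a[0].sequence)
    for h in list(haps_a) + list(haps_b):
        if len(h.sequence) != length:
            raise InputError("haplotype length mismatch")
    matrix = np.array(
        [[hamming(a.sequence, b.sequence) for b in haps_b] for a in haps_a],
        dtype=int,
    )
    seqs_a = [h.sequence for h in haps_a]
    seqs_b = [h.sequence for h in haps_b]
    n_fixed = 0
    for pos in range(length):
        sa = _column_states(seqs_a, pos)
        sb = _column_states(seqs_b, pos)
        if sa and sb and not (sa & sb) and len(sa | sb) >= 2:
            n_fixed += 1
    return {
        "matrix": matrix,
        "mean_between": float(matrix.mean()),
        "fixed_count": n_fixed,
    }


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_msn(
    haps: Sequence[Haplotype],
    tm_by_node: Mapping[int, float] | None = None,
) -> HaplotypeNetwork:
    """Minimum spanning network over haplotype Hamming distances.

    Kruskal over ascending edge weights; within each weight class, every edge
    that joins two components *as they stood at the start of that weight
    class* is retained — the first such edge per component pair as a spanning
    edge, equal-weight ties as alternative edges. This keeps the reticulations
    a strict spanning tree would drop.
    """
    n = len(haps)
    if n == 0:
        raise InputError("no haplotypes")
    if n == 1:
        warnings.warn("single haplotype: degenerate network with no edges", stacklevel=2)
        return HaplotypeNetwork(list(haps), [], dict(tm_by_node or {}))
    all_edges = sorted(
        (hamming(haps[i].sequence, haps[j].sequence), i, j)
        for i, j in itertools.combinations(range(n), 2)
    )
    uf = _UnionFind(n)
    edges: list[tuple[int, int, int, bool]] = []
    for weight, group in itertools.groupby(all_edges, key=lambda e: e[0]):
        group = list(group)
        # component labels frozen at the start of this weight class
        comp_at_start = [uf.find(i) for i in range(n)]
        candidates = [
            (w, i, j)
            for w, i, j in group
            if comp_at_start[i] != comp_at_start[j]
        ]
        for w, i, j in candidates:
            merged = uf.union(i, j)
            edges.append((i, j, w, not merged))
        if all(uf.find(i) == uf.find(0) for i in range(n)):
            break
    return HaplotypeNetwork(list(haps), edges, dict(tm_by_node or {}))
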