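"""Anchor-centred local synteny: neighborhoods, best-hit maps, conserved blocks.

Around an anchor gene (e.g. a synuclein), the flanking genes — by default
five on each side — are extracted in chromosomal order, each flanking gene
is mapped to its best cross-genome subject with the same tie rules as the
chromosome-scale classifier, and neighborhoods are compared:

* congruence of two neighborhoods = how many homology families they share,
  how similar the order of those families is (|Kendall tau|, so an exact
  reversal — a chromosomal inversion — still scores 1), and how consistent
  the relative gene orientations are;
* conserved blocks = maximal runs of homology families that appear, in
  order (forward or reversed), in at least ``min_members`` neighborhoods,
  allowing a small budget of intervening unlabelled genes.

A homology *family* is a connected component of the best-hit links
restricted to the compared neighborhoods, so near-duplicate subjects (the
MMRN1/MMRN2 kind) collapse to one label when the hits link them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .classify import DEFAULT_EVALUE_THRESHOLD, summarize_query
from .io import GeneLocation, HitRecord, locations_by_gene

__all__ = [
    "Neighborhood",
    "MappedGene",
    "NeighborhoodMapping",
    "ConservedBlock",
    "CongruenceResult",
    "extract_neighborhood",
    "map_neighborhood",
    "identity_mapping",
    "assign_families",
    "congruence_scores",
    "find_conserved_blocks",
]


@dataclass(frozen=True)
class Neighborhood:
    """An anchor gene and up to ``half_width`` flanking genes on each side."""

    anchor: str
    flank: tuple[GeneLocation, ...]  # includes the anchor, in rank order
    genome: str = ""
    truncated_left: bool = False
    truncated_right: bool = False

    def __post_init__(self) -> None:
        if self.anchor not in {g.gene_id for g in self.flank}:
            raise ValueError("anchor not contained in its own neighborhood")
        ranks = [g.rank for g in self.flank]
        if ranks != sorted(ranks):
            raise ValueError("neighborhood genes not in rank order")


def extract_neighborhood(
    locations: Iterable[GeneLocation] | Mapping[str, GeneLocation],
    anchor: str,
    half_width: int = 5,
    genome: str = "",
) -> Neighborhood:
    """Select up to *half_width* genes either side of *anchor* by rank.

    Truncation at a chromosome end is recorded in the flags rather than
    padded, so congruence denominators stay honest near chromosome ends.
    """
    index = (
        dict(locations)
        if isinstance(locations, Mapping)
        else locations_by_gene(locations)
    )
    if anchor not in index:
        raise KeyError(f"unknown anchor gene {anchor!r}")
    loc = index[anchor]
    chrom_genes = sorted(
        (g for g in index.values() if g.chromosome == loc.chromosome),
        key=lambda g: g.rank,
    )
    i = next(k for k, g in enumerate(chrom_genes) if g.gene_id == anchor)
    lo = max(0, i - half_width)
    hi = min(len(chrom_genes), i + half_width + 1)
    return Neighborhood(
        anchor=anchor,
        flank=tuple(chrom_genes[lo:hi]),
        genome=genome,
        truncated_left=(i - lo) < half_width,
        truncated_right=(hi - 1 - i) < half_width,
    )


@dataclass(frozen=True)
class MappedGene:
    """One flank gene and its best cross-genome subject (or no hit)."""

    gene_id: str
    query_strand: str
    subject_gene: str | None
    subject_chromosome: str | None
    same_orientation: bool | None  # query strand == subject strand

    @property
    def has_hit(self) -> bool:
        return self.subject_gene is not None


@dataclass(frozen=True)
class NeighborhoodMapping:
    """A neighborhood with every flank gene mapped to its best subject."""

    neighborhood: Neighborhood
    entries: tuple[MappedGene, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != len(self.neighborhood.flank):
            raise ValueError("one mapping entry required per flank gene")


def map_neighborhood(
    neighborhood: Neighborhood,
    hits: Iterable[HitRecord],
    subject_locations: Iterable[GeneLocation] | Mapping[str, GeneLocation],
    significance_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> NeighborhoodMapping:
    """Map each flank gene to its rank-1 subject under the classifier tie rules."""
    sub_index = (
        dict(subject_locations)
        if isinstance(subject_locations, Mapping)
        else locations_by_gene(subject_locations)
    )
    grouped: dict[str, list[HitRecord]] = {}
    for h in hits:
        query = h.query_gene if h.query_gene is not None else h.query_protein
        grouped.setdefault(query, []).append(h)

    entries: list[MappedGene] = []
    for g in neighborhood.flank:
        summary = summarize_query(grouped.get(g.gene_id, []), significance_threshold)
        if summary.top_subject is None:
            entries.append(MappedGene(g.gene_id, g.strand, None, None, None))
            continue
        subject = summary.top_subject
        sub_loc = sub_index.get(subject)
        entries.append(
            MappedGene(
                gene_id=g.gene_id,
                query_strand=g.strand,
                subject_gene=subject,
                subject_chromosome=sub_loc.chromosome if sub_loc else None,
                same_orientation=(g.strand == sub_loc.strand) if sub_loc else None,
            )
        )
    return NeighborhoodMapping(neighborhood, tuple(entries))


def identity_mapping(neighborhood: Neighborhood) -> NeighborhoodMapping:
    """Map a neighborhood onto itself (reference genome as its own subject)."""
    return NeighborhoodMapping(
        neighborhood,
        tuple(
            MappedGene(g.gene_id, g.strand, g.gene_id, g.chromosome, True)
            for g in neighborhood.flank
        ),
    )


# ---------------------------------------------------------------------------
# homology families

def assign_families(
    mappings: Sequence[NeighborhoodMapping],
) -> list[list[str | None]]:
    """Label every flank gene with its homology family, per neighborhood.

    Families are connected components of the bipartite graph linking each
    flank gene to its best subject, restricted to the given neighborhoods.
    The family label is the lexicographically smallest subject gene id in
    the component (falling back to the smallest node id), which gives
    human-readable labels when subjects are named genes.  Genes without a
    hit get ``None``.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    subjects: set[str] = set()
    for m in mappings:
        for e in m.entries:
            if e.subject_gene is not None:
                q_node = f"{m.neighborhood.genome}\x00{e.gene_id}"
                union(q_node, f"S\x00{e.subject_gene}")
                subjects.add(e.subject_gene)

    # canonical label per component: smallest subject gene id in it
    members: dict[str, list[str]] = {}
    for node in list(parent):
        members.setdefault(find(node), []).append(node)
    label_of_root: dict[str, str] = {}
    for root, nodes in members.items():
        subject_names = sorted(
            n.split("\x00", 1)[1] for n in nodes if n.startswith("S\x00")
        )
        label_of_root[root] = subject_names[0] if subject_names else min(nodes)

    out: list[list[str | None]] = []
    for m in mappings:
        labels: list[str | None] = []
        for e in m.entries:
            if e.subject_gene is None:
                labels.append(None)
            else:
                labels.append(
                    label_of_root[find(f"{m.neighborhood.genome}\x00{e.gene_id}")]
                )
        out.append(labels)
    return out


# ---------------------------------------------------------------------------
# congruence

@dataclass(frozen=True)
class CongruenceResult:
    shared: int
    order_score: float | None  # |Kendall tau|; None when shared < 2
    orientation_score: float | None
    reversed_order: bool


def congruence_scores(
    mapping_1: NeighborhoodMapping, mapping_2: NeighborhoodMapping
) -> CongruenceResult:
    """Order and polarity congruence of two mapped neighborhoods.

    Shared families are ordered by first occurrence in each neighborhood;
    the order score is the absolute Kendall tau between the two orderings,
    so an exact reversal (inversion) scores 1.  Orientation consistency is
    judged in the frame of the better-aligned direction: when the order
    correlation is negative the block is treated as inverted and flipped
    relative orientations count as consistent.
    """
    fams_1, fams_2 = assign_families([mapping_1, mapping_2])

    def first_occurrence(
        labels: list[str | None], mapping: NeighborhoodMapping
    ) -> dict[str, tuple[int, bool | None]]:
        out: dict[str, tuple[int, bool | None]] = {}
        for pos, (lab, entry) in enumerate(zip(labels, mapping.entries)):
            if lab is not None and lab not in out:
                out[lab] = (pos, entry.same_orientation)
        return out

    occ_1 = first_occurrence(fams_1, mapping_1)
    occ_2 = first_occurrence(fams_2, mapping_2)
    shared = sorted(set(occ_1) & set(occ_2))
    if len(shared) < 2:
        ori = None
        if len(shared) == 1:
            f = shared[0]
            if occ_1[f][1] is not None and occ_2[f][1] is not None:
                ori = 1.0 if occ_1[f][1] == occ_2[f][1] else 0.0
        return CongruenceResult(len(shared), None, ori, False)

    pos_1 = [occ_1[f][0] for f in shared]
    pos_2 = [occ_2[f][0] for f in shared]
    tau = stats.kendalltau(pos_1, pos_2).statistic
    tau = 0.0 if tau != tau else float(tau)  # NaN only for degenerate ties
    is_reversed = tau < 0

    consistent = 0
    judged = 0
    for f in shared:
        o1, o2 = occ_1[f][1], occ_2[f][1]
        if o1 is None or o2 is None:
            continue
        judged += 1
        agree = o1 == o2
        if agree != is_reversed:  # agree in forward frame, flipped in reversed
            consistent += 1
    return CongruenceResult(
        shared=len(shared),
        order_score=abs(tau),
        orientation_score=(consistent / judged) if judged else None,
        reversed_order=is_reversed,
    )


# ---------------------------------------------------------------------------
# conserved blocks

@dataclass(frozen=True)
class ConservedBlock:
    """A maximal ordered run of families shared by several neighborhoods."""

    families: tuple[str, ...]
    members: frozenset[str]

    @property
    def length(self) -> int:
        return len(self.families)


def _labelled_runs(labels: Sequence[str | None], gap_budget: int):
    """Positions/labels of family genes, split where unlabelled gaps exceed budget."""
    pts = [(i, lab) for i, lab in enumerate(labels) if lab is not None]
    runs: list[list[tuple[int, str]]] = []
    for pt in pts:
        if runs and pt[0] - runs[-1][-1][0] - 1 <= gap_budget:
            runs[-1].append(pt)
        else:
            runs.append([pt])
    return runs


def _contains(
    labels: Sequence[str | None], pattern: tuple[str, ...], gap_budget: int
) -> bool:
    """Does *pattern* occur forward or reversed as a gap-bounded family run?"""
    for cand in (pattern, pattern[::-1]):
        for run in _labelled_runs(labels, gap_budget):
            run_labels = tuple(lab for _i, lab in run)
            for start in range(len(run_labels) - len(cand) + 1):
                if run_labels[start:start + len(cand)] == cand:
                    return True
        if pattern == pattern[::-1]:
            break
    return False


def find_conserved_blocks(
    family_sequences: Mapping[str, Sequence[str | None]],
    min_members: int = 2,
    min_length: int = 2,
    gap_budget: int = 2,
) -> set[ConservedBlock]:
    """Find maximal family blocks shared by ``>= min_members`` neighborhoods.

    *family_sequences* maps a neighborhood id to its rank-ordered family
    labels (``None`` for genes outside any family).  A block is a tuple of
    families occurring as consecutive family-labelled genes — with at most
    *gap_budget* unlabelled genes between neighbours — forward or reversed,
    in every member.  Reported blocks are maximal: any block whose family
    tuple is a sub-run of a longer reported block with at least the same
    members is suppressed.
    """
    candidates: set[tuple[str, ...]] = set()
    for labels in family_sequences.values():
        for run in _labelled_runs(labels, gap_budget):
            run_labels = tuple(lab for _i, lab in run)
            n = len(run_labels)
            for i in range(n):
                for j in range(i + min_length, n + 1):
                    window = run_labels[i:j]
                    candidates.add(min(window, window[::-1]))

    scored: list[ConservedBlock] = []
    for cand in candidates:
        members = frozenset(
            nid
            for nid, labels in family_sequences.items()
            if _contains(labels, cand, gap_budget)
        )
        if len(members) >= min_members:
            scored.append(ConservedBlock(cand, members))

    def is_subrun(short: tuple[str, ...], long: tuple[str, ...]) -> bool:
        for cand in (short, short[::-1]):
            if any(
                long[i:i + len(cand)] == cand
                for i in range(len(long) - len(cand) + 1)
            ):
                return True
        return False

    maximal: set[ConservedBlock] = set()
    for block in scored:
        dominated = any(
            other.length > block.length
            and other.members >= block.members
            and is_subrun(block.families, other.families)
            for other in scored
        )
        if not dominated:
            maximal.add(block)
    return maximal
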