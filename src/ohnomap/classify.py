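"""Best-hit classification: per-query summaries and the top/total/solo matrix.

For every query gene, hits are filtered at a significance threshold,
collapsed over subject isoforms to distinct subject *genes*, ranked, and
truncated to the three highest-scoring subjects.  A query is *solo* when
exactly one distinct significant subject gene exists — evaluated before
truncation, so a query with four weak distinct subjects is not solo.

Aggregation over a chromosome of query genes gives, per subject chromosome:

* ``top``   — queries whose single best hit lies there,
* ``total`` — queries any of whose three best subjects lie there
  (counted once per query per chromosome),
* ``solo``  — solo queries whose unique subject lies there.

Ties are broken deterministically: bit score descending, then E-value
ascending, then subject gene id ascending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import GeneLocation, HitRecord, locations_by_gene

__all__ = [
    "DEFAULT_EVALUE_THRESHOLD",
    "QueryHitSummary",
    "CountMatrix",
    "summarize_query",
    "summarize_hits",
    "build_count_matrix",
    "closest_paralog_counts",
    "NO_PARALOG",
]

#: Default hit-significance cutoff (E-value); configurable everywhere and
#: echoed in report headers, since "significant hit" admits no single value.
DEFAULT_EVALUE_THRESHOLD = 1e-5

#: Key under which queries with no (non-self) significant hit are tallied.
NO_PARALOG = "__no_paralog__"


@dataclass(frozen=True)
class QueryHitSummary:
    """The ≤3 best distinct subject genes of one query, plus the solo flag."""

    query_gene: str
    best_subjects: tuple[tuple[str, float, float], ...]  # (gene, bits, evalue)
    is_solo: bool

    def __post_init__(self) -> None:
        genes = [s[0] for s in self.best_subjects]
        if len(genes) != len(set(genes)):
            raise ValueError("best subjects not distinct")
        scores = [s[1] for s in self.best_subjects]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("subject scores not non-increasing")
        if self.is_solo and len(self.best_subjects) != 1:
            raise ValueError("solo summary must have exactly one subject")

    @property
    def top_subject(self) -> str | None:
        return self.best_subjects[0][0] if self.best_subjects else None


def _resolve_subject(hit: HitRecord, protein_to_gene: Mapping[str, str] | None) -> str:
    gene = hit.subject_gene
    if protein_to_gene is not None:
        gene = protein_to_gene.get(hit.subject_protein, gene)
    return gene if gene is not None else hit.subject_protein


def summarize_query(
    hits: Sequence[HitRecord],
    significance_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    protein_to_gene: Mapping[str, str] | None = None,
) -> QueryHitSummary:
    """Reduce one query's hits to its :class:`QueryHitSummary`.

    Isoform hits are collapsed first (per subject gene, keep the maximum bit
    score and, among ties, the minimum E-value), then ranked and truncated
    to three.  Empty input yields an empty, non-solo summary.
    """
    queries = {
        h.query_gene if h.query_gene is not None else h.query_protein for h in hits
    }
    if len(queries) > 1:
        raise ValueError(f"hits span multiple query genes: {sorted(queries)}")
    query = queries.pop() if queries else ""

    best: dict[str, tuple[float, float]] = {}
    for h in hits:
        if h.e_value > significance_threshold:
            continue
        gene = _resolve_subject(h, protein_to_gene)
        cur = best.get(gene)
        cand = (h.bit_score, h.e_value)
        if cur is None or (cand[0], -cand[1]) > (cur[0], -cur[1]):
            best[gene] = cand
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[0]))
    is_solo = len(ranked) == 1
    return QueryHitSummary(
        query_gene=query,
        best_subjects=tuple((g, s, e) for g, (s, e) in ranked[:3]),
        is_solo=is_solo,
    )


def summarize_hits(
    hits: Iterable[HitRecord],
    significance_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    protein_to_gene: Mapping[str, str] | None = None,
) -> list[QueryHitSummary]:
    """Group hits by query gene and summarize each; queries sorted by id."""
    grouped: dict[str, list[HitRecord]] = {}
    for h in hits:
        query = h.query_gene if h.query_gene is not None else h.query_protein
        if protein_to_gene is not None:
            query = protein_to_gene.get(h.query_protein, query)
        grouped.setdefault(query, []).append(
            h if h.query_gene == query else _with_query_gene(h, query)
        )
    return [
        summarize_query(grouped[q], significance_threshold, protein_to_gene)
        for q in sorted(grouped)
    ]


def _with_query_gene(hit: HitRecord, gene: str) -> HitRecord:
    import dataclasses

    return dataclasses.replace(hit, query_gene=gene)


# ---------------------------------------------------------------------------
# the top/total/solo count matrix

@dataclass
class CountMatrix:
    """Per (query chromosome × subject chromosome) top/total/solo gene counts.

    ``denominators[qc] = (n_queries_with_hits, n_solo_queries)`` so that the
    column sums are auditable: per query chromosome, the ``top`` counts sum
    to the number of queries with hits and ``solo`` to the solo queries.
    """

    counts: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    denominators: dict[str, tuple[int, int]] = field(default_factory=dict)

    def cell(self, query_chrom: str, subject_chrom: str) -> dict[str, int]:
        return self.counts.get(
            (query_chrom, subject_chrom), {"top": 0, "total": 0, "solo": 0}
        )

    @property
    def query_chromosomes(self) -> list[str]:
        return sorted({qc for qc, _ in self.counts} | set(self.denominators))

    @property
    def subject_chromosomes(self) -> list[str]:
        return sorted({sc for _, sc in self.counts})

    def column(self, query_chrom: str, column: str) -> dict[str, int]:
        """All subject-chromosome counts of one column for one query chromosome."""
        if column not in ("top", "total", "solo"):
            raise KeyError(column)
        return {
            sc: self.counts[(qc, sc)][column]
            for (qc, sc) in self.counts
            if qc == query_chrom
        }

    def validate(self) -> None:
        for (qc, sc), cell in self.counts.items():
            if not (0 <= cell["solo"] <= cell["top"] <= cell["total"]):
                raise AssertionError(
                    f"cell ({qc},{sc}) violates solo<=top<=total: {cell}"
                )
        for qc in self.query_chromosomes:
            n_hits, n_solo = self.denominators.get(qc, (0, 0))
            tops = sum(self.column(qc, "top").values())
            solos = sum(self.column(qc, "solo").values())
            totals = sum(self.column(qc, "total").values())
            if tops != n_hits or solos != n_solo or totals > 3 * n_hits:
                raise AssertionError(
                    f"query chromosome {qc}: column sums {tops}/{totals}/{solos} "
                    f"inconsistent with denominators {n_hits}/{n_solo}"
                )

    # -- serialization (Table-2-style layout: rows = subject chromosomes,
    #    column triples per query chromosome) --------------------------------

    def to_tsv(self, path, comment_lines: Sequence[str] = ()) -> None:
        qcs = self.query_chromosomes
        scs = self.subject_chromosomes
        with open(path, "w") as fh:
            for line in comment_lines:
                fh.write(f"# {line}\n")
            header = ["subject_chromosome"]
            for qc in qcs:
                header += [f"{qc}:top", f"{qc}:total", f"{qc}:solo"]
            fh.write("\t".join(header) + "\n")
            for sc in scs:
                row = [sc]
                for qc in qcs:
                    cell = self.cell(qc, sc)
                    row += [str(cell["top"]), str(cell["total"]), str(cell["solo"])]
                fh.write("\t".join(row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        with open(path) as fh:
            line = "#"
            while line.startswith("#"):
                line = fh.readline()
            header = line.rstrip("\n").split("\t")
            if header[0] != "subject_chromosome":
                raise ValueError(f"bad count-matrix header: {header[:1]}")
            triples: list[tuple[str, str]] = []
            for col in header[1:]:
                qc, kind = col.rsplit(":", 1)
                triples.append((qc, kind))
            matrix = cls()
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if not fields or fields == [""]:
                    continue
                sc = fields[0]
                for (qc, kind), value in zip(triples, fields[1:]):
                    key = (qc, sc)
                    cell = matrix.counts.setdefault(
                        key, {"top": 0, "total": 0, "solo": 0}
                    )
                    cell[kind] = int(value)
        for qc in matrix.query_chromosomes:
            matrix.denominators[qc] = (
                sum(matrix.column(qc, "top").values()),
                sum(matrix.column(qc, "solo").values()),
            )
        return matrix


def build_count_matrix(
    summaries: Iterable[QueryHitSummary],
    subject_locations: Iterable[GeneLocation] | Mapping[str, GeneLocation],
    query_locations: Iterable[GeneLocation] | Mapping[str, GeneLocation],
) -> CountMatrix:
    """Aggregate query summaries into the top/total/solo matrix.

    Per query: +1 ``top`` on its rank-1 subject's chromosome; +1 ``total``
    on every chromosome appearing among its ≤3 subjects (at most once per
    query per chromosome); if solo, +1 ``solo`` on that chromosome.
    """
    sub_index = (
        dict(subject_locations)
        if isinstance(subject_locations, Mapping)
        else locations_by_gene(subject_locations)
    )
    qry_index = (
        dict(query_locations)
        if isinstance(query_locations, Mapping)
        else locations_by_gene(query_locations)
    )

    summaries = list(summaries)
    missing = sorted(
        {
            s[0]
            for summ in summaries
            for s in summ.best_subjects
            if s[0] not in sub_index
        }
        | {s.query_gene for s in summaries if s.query_gene not in qry_index}
    )
    if missing:
        raise KeyError(f"unlocatable genes: {', '.join(missing)}")

    matrix = CountMatrix()
    for summ in summaries:
        qc = qry_index[summ.query_gene].chromosome
        n_hits, n_solo = matrix.denominators.get(qc, (0, 0))
        if not summ.best_subjects:
            matrix.denominators[qc] = (n_hits, n_solo)
            continue
        matrix.denominators[qc] = (n_hits + 1, n_solo + (1 if summ.is_solo else 0))
        subject_chroms = [sub_index[s[0]].chromosome for s in summ.best_subjects]
        top_chrom = subject_chroms[0]

        def bump(sc: str, kind: str) -> None:
            cell = matrix.counts.setdefault(
                (qc, sc), {"top": 0, "total": 0, "solo": 0}
            )
            cell[kind] += 1

        bump(top_chrom, "top")
        for sc in dict.fromkeys(subject_chroms):  # dedup, order-preserving
            bump(sc, "total")
        if summ.is_solo:
            bump(top_chrom, "solo")
    return matrix


# ---------------------------------------------------------------------------
# within-genome closest paralogs

def closest_paralog_counts(
    within_hits: Iterable[HitRecord],
    locations: Iterable[GeneLocation] | Mapping[str, GeneLocation],
    region: str | Iterable[str],
    significance_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    protein_to_gene: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Attribute each region gene to the chromosome of its closest paralog.

    *region* is either a chromosome id or an explicit set of gene ids.  For
    every query gene in the region with at least one significant non-self
    hit, the chromosome of its best non-self subject (same tie rules as the
    cross-genome classifier) gains one count; queries whose only hit is
    themselves (or with no significant hit at all) are tallied under
    :data:`NO_PARALOG`.
    """
    index = (
        dict(locations)
        if isinstance(locations, Mapping)
        else locations_by_gene(locations)
    )
    if isinstance(region, str):
        region_genes = {g for g, loc in index.items() if loc.chromosome == region}
    else:
        region_genes = set(region)

    grouped: dict[str, list[HitRecord]] = {g: [] for g in region_genes}
    for h in within_hits:
        query = h.query_gene if h.query_gene is not None else h.query_protein
        if protein_to_gene is not None:
            query = protein_to_gene.get(h.query_protein, query)
        if query not in region_genes:
            continue
        subject = _resolve_subject(h, protein_to_gene)
        if subject == query:  # self-hit
            continue
        grouped[query].append(_with_query_gene(h, query))

    counts: dict[str, int] = {}
    for query in sorted(region_genes):
        summ = summarize_query(
            grouped[query], significance_threshold, protein_to_gene
        )
        if summ.top_subject is None:
            counts[NO_PARALOG] = counts.get(NO_PARALOG, 0) + 1
            continue
        if summ.top_subject not in index:
            raise KeyError(f"unlocatable genes: {summ.top_subject}")
        chrom = index[summ.top_subject].chromosome
        counts[chrom] = counts.get(chrom, 0) + 1
    return counts
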