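"""Macrosynteny association tests between query and subject chromosomes.

The central question — do two query-genome chromosomes differ in how their
genes distribute over two WGD-derived groups of subject chromosomes? — is
answered with 2×2 contingency tables.  Subject chromosomes are pooled into
the two groups descended from the duplicated ancestral chromosome (for the
human genome these default to {4, 5} versus {2, 8, 10}, both tracing back
to the proto-vertebrate chromosome CLGQ/Pvc8), and a Pearson chi-square
with one degree of freedom is computed *without* continuity correction.

Because gene retention after WGD varies enormously between chromosomes,
raw per-chromosome counts are not comparable across query chromosomes;
the pooled 2×2 design cancels the retention differences out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy import stats

from .classify import CountMatrix
from .io import GeneLocation, OhnologPair, locations_by_gene

__all__ = [
    "ChromosomeGroups",
    "ContingencyTable2x2",
    "ChiSquareResult",
    "DegenerateTableError",
    "pool_counts",
    "pearson_chi_square",
    "monte_carlo_p",
    "fraction_on_group",
    "count_group_sum",
    "count_ohnolog_pairs",
    "UNPLACED",
]

#: Bucket for ohnolog pairs with an unlocatable member.
UNPLACED = "__unplaced__"


class DegenerateTableError(ValueError):
    """A contingency table with a zero marginal cannot be tested."""


@dataclass(frozen=True)
class ChromosomeGroups:
    """Two disjoint sets of subject chromosomes descended from one ancestor.

    Defaults encode the human descendants of CLGQ/Pvc8: one post-WGD1 copy
    surviving on chromosomes 4 and 5, the other fragmented over 2, 8 and 10.
    """

    group_a: frozenset[str] = frozenset({"4", "5"})
    group_b: frozenset[str] = frozenset({"2", "8", "10"})
    ancestral_label: str = "CLGQ/Pvc8"

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("chromosome groups must be non-empty")
        if self.group_a & self.group_b:
            raise ValueError(
                f"groups overlap: {sorted(self.group_a & self.group_b)}"
            )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = the two chromosome groups; columns = the two query chromosomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def pool_counts(
    matrix: CountMatrix,
    query_chromosomes: tuple[str, str],
    groups: ChromosomeGroups | None = None,
    column: str = "top",
) -> ContingencyTable2x2:
    """Pool one column of the count matrix into the group-by-chromosome table.

    Subject chromosomes outside both groups are ignored.  Cell (group,
    query chromosome) is the sum of the chosen column over group members.
    """
    groups = groups or ChromosomeGroups()
    q1, q2 = query_chromosomes
    present = set(matrix.query_chromosomes)
    missing = [q for q in (q1, q2) if q not in present]
    if missing:
        raise KeyError(f"query chromosomes not in matrix: {missing}")

    def total(qc: str, members: frozenset[str]) -> int:
        col = matrix.column(qc, column)
        return sum(col.get(sc, 0) for sc in members)

    return ContingencyTable2x2(
        a=total(q1, groups.group_a),
        b=total(q2, groups.group_a),
        c=total(q1, groups.group_b),
        d=total(q2, groups.group_b),
    )


def pearson_chi_square(table: ContingencyTable2x2) -> ChiSquareResult:
    """Pearson chi-square, df=1, no continuity correction.

    Closed form N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d)); p is the upper tail of
    the chi-square distribution with one degree of freedom.
    """
    if any(m == 0 for m in table.marginals):
        raise DegenerateTableError(
            f"degenerate table (zero marginal): {table.as_rows()}"
        )
    a, b, c, d = table.a, table.b, table.c, table.d
    num = table.n * (a * d - b * c) ** 2
    den = 1
    for m in table.marginals:
        den *= m
    statistic = num / den
    p = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(statistic=float(statistic), df=1, p_value=p)


def monte_carlo_p(
    table: ContingencyTable2x2,
    draws: int = 100_000,
    seed: int = 0,
    conditional: bool = False,
) -> tuple[float, float]:
    """Monte-Carlo p-value for the Pearson statistic, with its standard error.

    ``conditional=False`` (default) samples tables from the independence
    model with both margins estimated (multinomial null) — the sampling
    model whose statistic the chi-square(1) distribution approximates.
    ``conditional=True`` fixes both margins (hypergeometric / label
    permutation null); note that on any fixed table this exact null differs
    from the asymptotic p by more than Monte-Carlo error, because the
    statistic's conditional support is discrete.
    """
    import numpy as np

    if any(m == 0 for m in table.marginals):
        raise DegenerateTableError(
            f"degenerate table (zero marginal): {table.as_rows()}"
        )
    rng = np.random.default_rng(seed)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    obs = pearson_chi_square(table).statistic
    if conditional:
        r1, r2, c1 = a + b, c + d, a + c
        av = rng.hypergeometric(r1, r2, c1, size=draws).astype(float)
        bv, cv = r1 - av, c1 - av
        dv = r2 - cv
        denom = float(r1) * r2 * c1 * (n - c1)
        stat = n * (av * dv - bv * cv) ** 2 / denom
    else:
        r1, r2 = (a + b) / n, (c + d) / n
        c1, c2 = (a + c) / n, (b + d) / n
        cells = rng.multinomial(
            n, [r1 * c1, r1 * c2, r2 * c1, r2 * c2], size=draws
        ).astype(float)
        av, bv, cv, dv = cells.T
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = n * (av * dv - bv * cv) ** 2 / (
                (av + bv) * (cv + dv) * (av + cv) * (bv + dv)
            )
        stat = np.nan_to_num(stat)  # a degenerate draw has statistic 0
    p = float(np.mean(stat >= obs - 1e-12))
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / draws))
    return p, se


def fraction_on_group(
    matrix: CountMatrix,
    query_chromosome: str,
    chromosomes: Iterable[str],
    column: str = "top",
) -> float:
    """Percentage of the column falling on the named subject chromosomes.

    100 × (sum over the named set) / (sum over *all* subject chromosomes);
    the conventional report rounds to the nearest integer.
    """
    col = matrix.column(query_chromosome, column)
    if not col:
        raise KeyError(f"query chromosome {query_chromosome!r} not in matrix")
    denominator = sum(col.values())
    if denominator == 0:
        raise ZeroDivisionError(
            f"no {column} counts for query chromosome {query_chromosome!r}"
        )
    numerator = sum(col.get(sc, 0) for sc in set(chromosomes))
    return 100.0 * numerator / denominator


def count_group_sum(
    matrix: CountMatrix,
    query_chromosome: str,
    chromosomes: Iterable[str],
    column: str = "top",
) -> int:
    """Integer numerator of :func:`fraction_on_group`."""
    col = matrix.column(query_chromosome, column)
    if not col:
        raise KeyError(f"query chromosome {query_chromosome!r} not in matrix")
    return sum(col.get(sc, 0) for sc in set(chromosomes))


def count_ohnolog_pairs(
    pairs: Iterable[OhnologPair],
    locations: Iterable[GeneLocation] | Mapping[str, GeneLocation],
) -> dict[frozenset[str], int]:
    """Tally ohnolog pairs per unordered chromosome pair.

    Each pair increments exactly one bucket (same-chromosome pairs fall in
    a singleton-set bucket); pairs with an unlocatable member are tallied
    under the :data:`UNPLACED` singleton bucket rather than dropped.
    """
    index = (
        dict(locations)
        if isinstance(locations, Mapping)
        else locations_by_gene(locations)
    )
    counts: dict[frozenset[str], int] = {}
    for pair in pairs:
        if pair.gene_a in index and pair.gene_b in index:
            key = frozenset(
                {index[pair.gene_a].chromosome, index[pair.gene_b].chromosome}
            )
        else:
            key = frozenset({UNPLACED})
        counts[key] = counts.get(key, 0) + 1
    return counts
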