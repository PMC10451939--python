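"""End-to-end orchestration: config, one reproducible run, report bundle.

A run starts from exactly one of three input sources — a precomputed
top/total/solo count matrix, raw hit tables plus gene locations, or a
simulation — and produces the count matrix, the pooled 2×2 chi-square
report, and the group-fraction report.  Every output records the config
hash, seeds and significance threshold in comment headers, so a report is
auditable back to its exact configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import simulate as sim
from .association import (
    ChiSquareResult,
    ChromosomeGroups,
    ContingencyTable2x2,
    DegenerateTableError,
    count_group_sum,
    fraction_on_group,
    pearson_chi_square,
    pool_counts,
)
from .classify import (
    DEFAULT_EVALUE_THRESHOLD,
    CountMatrix,
    build_count_matrix,
    summarize_hits,
)
from .io import read_gene_table, read_outfmt6, read_protein_gene_map

__all__ = [
    "RunConfig",
    "ConfigError",
    "ReportBundle",
    "run_pipeline",
    "default_simulation_schedule",
    "packaged_count_matrix",
]

#: Packaged fixture: printed per-chromosome top/total/solo counts for the
#: sea-lamprey chromosomes 8, 41 and 22 compared against the human proteome.
_PACKAGED_COUNTS = Path(__file__).parent / "data" / "petromyzon_human_counts.tsv"


class ConfigError(ValueError):
    pass


def packaged_count_matrix() -> CountMatrix:
    return CountMatrix.from_tsv(_PACKAGED_COUNTS)


@dataclass
class RunConfig:
    """Everything one run needs; round-trips through YAML unchanged.

    Exactly one of (``count_matrix``), (``hit_table`` + ``query_genes`` +
    ``subject_genes``), (``simulation``) must be set.
    """

    count_matrix: str | None = None
    hit_table: str | None = None
    query_genes: str | None = None
    subject_genes: str | None = None
    protein_gene_map: str | None = None
    simulation: dict[str, Any] | None = None

    significance_threshold: float = DEFAULT_EVALUE_THRESHOLD
    group_a: list[str] = field(default_factory=lambda: ["4", "5"])
    group_b: list[str] = field(default_factory=lambda: ["2", "8", "10"])
    ancestral_label: str = "CLGQ/Pvc8"
    query_pairs: list[list[str]] = field(
        default_factory=lambda: [["8", "41"], ["8", "22"]]
    )
    columns: list[str] = field(default_factory=lambda: ["top", "total", "solo"])
    seed: int = 0
    output_dir: str = "ohnomap_out"

    def __post_init__(self) -> None:
        sources = [
            self.count_matrix is not None,
            self.hit_table is not None,
            self.simulation is not None,
        ]
        if sum(sources) != 1:
            raise ConfigError(
                "exactly one input source required: count_matrix, hit_table "
                "or simulation"
            )
        if self.hit_table is not None and (
            self.query_genes is None or self.subject_genes is None
        ):
            raise ConfigError("hit_table input requires query_genes and subject_genes")

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def groups(self) -> ChromosomeGroups:
        return ChromosomeGroups(
            frozenset(self.group_a), frozenset(self.group_b), self.ancestral_label
        )


def default_simulation_schedule(
    retention: float, seed: int, per_chromosome: dict[str, float] | None = None
) -> sim.EventSchedule:
    """The canonical two-round history: WGD1, split, subject-lineage WGD2.

    Loss epochs with the given retention follow WGD1 (shared), the split
    (both lineages) and WGD2 (subject lineage).
    """
    loss = sim.LossEpoch(retention, per_chromosome or {})
    return sim.EventSchedule(
        shared=(sim.WGD(2), loss),
        lineage_a=(loss,),
        lineage_b=(sim.WGD(2), loss),
        seed=seed,
    )


@dataclass
class ReportBundle:
    matrix: CountMatrix
    chi_square: list[tuple[str, str, str, ContingencyTable2x2, ChiSquareResult | None]]
    fractions: list[tuple[str, str, int, float]]  # (query chrom, column, count, pct)
    output_dir: Path


def _require_file(path: str | None, what: str) -> Path:
    assert path is not None
    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"{what} file not found: {p}")
    return p


def _obtain_matrix(config: RunConfig) -> CountMatrix:
    if config.count_matrix is not None:
        return CountMatrix.from_tsv(_require_file(config.count_matrix, "count matrix"))
    if config.hit_table is not None:
        p2g = (
            read_protein_gene_map(_require_file(config.protein_gene_map, "protein map"))
            if config.protein_gene_map is not None
            else None
        )
        hits = read_outfmt6(
            _require_file(config.hit_table, "hit table"), p2g, strict=False
        )
        query_locs = read_gene_table(_require_file(config.query_genes, "query genes"))
        subject_locs = read_gene_table(
            _require_file(config.subject_genes, "subject genes")
        )
        summaries = summarize_hits(hits, config.significance_threshold, p2g)
        return build_count_matrix(summaries, subject_locs, query_locs)
    # simulation source
    params = dict(config.simulation or {})
    n_genes = int(params.pop("n_genes", 1000))
    n_chromosomes = int(params.pop("n_chromosomes", 1))
    retention = float(params.pop("retention", 0.7))
    noise_sd = float(params.pop("noise_sd", 0.0))
    decay = float(params.pop("decay_per_epoch", 10.0))
    seed = int(params.pop("seed", config.seed))
    if params:
        raise ConfigError(f"unknown simulation keys: {sorted(params)}")
    ancestral = sim.uniform_ancestral_genome(
        n_chromosomes, max(1, n_genes // n_chromosomes)
    )
    schedule = default_simulation_schedule(retention, seed)
    history = sim.simulate_history(ancestral, schedule)
    model = sim.SimilarityModel(decay_per_epoch=decay, noise_sd=noise_sd)
    hits = sim.emit_hit_table(history, model, seed=seed + 1)
    summaries = summarize_hits(hits, config.significance_threshold)
    return build_count_matrix(summaries, history.genome_b, history.genome_a)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run classification and association testing; write the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [
        f"config_hash: {config.config_hash}",
        f"seed: {config.seed}",
        f"significance_threshold: {config.significance_threshold}",
    ]

    matrix = _obtain_matrix(config)
    matrix.validate()
    matrix.to_tsv(out / "count_matrix.tsv", comment_lines=header)

    groups = config.groups()
    chi_rows: list[
        tuple[str, str, str, ContingencyTable2x2, ChiSquareResult | None]
    ] = []
    for q1, q2 in config.query_pairs:
        for column in config.columns:
            table = pool_counts(matrix, (q1, q2), groups, column)
            try:
                result = pearson_chi_square(table)
            except DegenerateTableError:
                result = None
            chi_rows.append((q1, q2, column, table, result))

    union = sorted(groups.group_a | groups.group_b)
    fraction_rows: list[tuple[str, str, int, float]] = []
    seen_chroms = sorted({q for pair in config.query_pairs for q in pair})
    for qc in seen_chroms:
        count = count_group_sum(matrix, qc, union, "top")
        pct = fraction_on_group(matrix, qc, union, "top")
        fraction_rows.append((qc, "top", count, pct))

    with (out / "chi_square_report.tsv").open("w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write(
            "# groups: {"
            + ",".join(sorted(groups.group_a))
            + "} vs {"
            + ",".join(sorted(groups.group_b))
            + f"}} (ancestral {groups.ancestral_label})\n"
        )
        fh.write("query_1\tquery_2\tcolumn\ta\tb\tc\td\tstatistic\tdf\tp\n")
        for q1, q2, column, table, result in chi_rows:
            stat = f"{result.statistic:.2f}" if result else "NA"
            p = f"{result.p_value:.3f}" if result else "NA"
            fh.write(
                f"{q1}\t{q2}\t{column}\t{table.a}\t{table.b}\t{table.c}\t{table.d}"
                f"\t{stat}\t1\t{p}\n"
            )

    with (out / "fraction_report.tsv").open("w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("query_chromosome\tcolumn\tchromosome_set\tcount\tpercent\n")
        for qc, column, count, pct in fraction_rows:
            fh.write(
                f"{qc}\t{column}\t{{{','.join(union)}}}\t{count}\t{round(pct)}\n"
            )

    return ReportBundle(
        matrix=matrix, chi_square=chi_rows, fractions=fraction_rows, output_dir=out
    )
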