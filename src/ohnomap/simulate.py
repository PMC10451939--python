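"""Ground-truthed simulation of genome evolution through whole-genome duplication.

The generator evolves a single ancestral genome through a shared sequence of
events (typically one whole-genome duplication, WGD1), splits it into two
lineages, and evolves each lineage independently (e.g. a gnathostome-style
WGD2, or an agnathan-style hexaploidization modelled as a single m=3 WGD),
with chromosome fusions, stochastic gene loss and gene transposition.  Every
extant gene carries its full copy path, so the true ortholog/paralog relation
and an ordinal divergence depth are known for every homologous pair.

A cross-genome pair is an *ortholog* iff the two genes descend from the same
copy produced by the shared (pre-split) WGDs — i.e. their copy paths agree on
every pre-split duplication.  Pairs that diverged at a pre-split WGD, and all
same-genome pairs, are *paralogs*.

Similarity is modelled directly in bit-score space (no sequence evolution):
score = base − decay·depth + Gaussian noise, with hits below a significance
floor suppressed and an E-value that decreases monotonically in the score.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .io import GeneLocation, HitRecord

__all__ = [
    "AncestralGenome",
    "WGD",
    "Fusion",
    "LossEpoch",
    "TranspositionEpoch",
    "EventSchedule",
    "SimulatedHistory",
    "SimilarityModel",
    "SimulationError",
    "simulate_history",
    "emit_hit_table",
    "uniform_ancestral_genome",
]

ORTHOLOG = "ortholog"
PARALOG = "paralog"

#: synthetic gene footprint used when materializing coordinates
_GENE_SPAN = 900
_GENE_STEP = 1000


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# inputs

@dataclass(frozen=True)
class AncestralGenome:
    """The pre-WGD genome: ordered chromosomes of ordered, stranded genes."""

    chromosomes: tuple[str, ...]
    genes_per_chromosome: Mapping[str, tuple[str, ...]]
    strands: Mapping[str, str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom in self.chromosomes:
            genes = self.genes_per_chromosome.get(chrom, ())
            if not genes:
                raise ValueError(f"chromosome {chrom!r} is empty")
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene id {g!r} not globally unique")
                seen.add(g)
                if self.strands.get(g) not in ("+", "-"):
                    raise ValueError(f"gene {g!r} lacks a valid strand")

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes_per_chromosome.values())


def uniform_ancestral_genome(
    n_chromosomes: int, genes_per_chromosome: int, prefix: str = "anc"
) -> AncestralGenome:
    """Convenience builder: equal-sized chromosomes, all genes on ``+``."""
    chroms = tuple(f"{prefix}{i + 1}" for i in range(n_chromosomes))
    genes = {
        c: tuple(f"{c}_g{j}" for j in range(genes_per_chromosome)) for c in chroms
    }
    strands = {g: "+" for gs in genes.values() for g in gs}
    return AncestralGenome(chroms, genes, strands)


@dataclass(frozen=True)
class WGD:
    """Whole-genome duplication with integer ploidy multiplier ``m`` >= 2."""

    multiplier: int = 2

    def __post_init__(self) -> None:
        if not isinstance(self.multiplier, int) or self.multiplier < 2:
            raise ValueError("WGD multiplier must be an integer >= 2")


@dataclass(frozen=True)
class Fusion:
    """Concatenate chromosome ``right`` onto the end of ``left``."""

    left: str
    right: str


@dataclass(frozen=True)
class LossEpoch:
    """Independent per-gene-copy survival with retention probability ``r``.

    ``per_chromosome`` overrides the retention rate on named chromosomes,
    which lets preferential retention (or deterministic copy loss, r=0) be
    expressed without extra event kinds.
    """

    retention: float = 1.0
    per_chromosome: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in (self.retention, *self.per_chromosome.values()):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retention {r} outside [0, 1]")

    def rate_for(self, chromosome: str) -> float:
        return self.per_chromosome.get(chromosome, self.retention)


@dataclass(frozen=True)
class TranspositionEpoch:
    """Each gene moves with probability ``q`` to a uniform chromosome/position.

    Strand is preserved with probability 1/2 on move (orientation stays
    informative but not deterministic).
    """

    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("transposition probability outside [0, 1]")


Event = WGD | Fusion | LossEpoch | TranspositionEpoch


@dataclass(frozen=True)
class EventSchedule:
    """Shared (pre-split) events, then per-lineage events, plus the seed."""

    shared: tuple[Event, ...] = ()
    lineage_a: tuple[Event, ...] = ()
    lineage_b: tuple[Event, ...] = ()
    seed: int = 0


# ---------------------------------------------------------------------------
# internal evolving state

@dataclass
class _Copy:
    ancestral: str
    strand: str
    # ((epoch, copy_index), ...) for every WGD this copy passed through
    path: tuple[tuple[int, int], ...]


_State = dict[str, list[_Copy]]  # chromosome -> ordered gene copies


def _apply_event(
    state: _State,
    event: Event,
    epoch: int,
    rng: np.random.Generator,
    lineage: str,
) -> None:
    if isinstance(event, WGD):
        new_state: _State = {}
        for chrom, genes in state.items():
            for k in range(event.multiplier):
                new_state[f"{chrom}.{k}"] = [
                    _Copy(g.ancestral, g.strand, g.path + ((epoch, k),))
                    for g in genes
                ]
        state.clear()
        state.update(new_state)
    elif isinstance(event, Fusion):
        for name in (event.left, event.right):
            if name not in state:
                raise SimulationError(
                    f"{lineage} epoch {epoch}: fusion names missing chromosome {name!r}"
                )
        fused = state.pop(event.left) + state.pop(event.right)
        state[f"{event.left}+{event.right}"] = fused
    elif isinstance(event, LossEpoch):
        for chrom in list(state):
            r = event.rate_for(chrom)
            kept = [g for g in state[chrom] if rng.random() < r]
            if kept:
                state[chrom] = kept
            else:
                del state[chrom]
        if not state:
            raise SimulationError(
                f"{lineage} epoch {epoch}: genome empty after loss epoch"
            )
    elif isinstance(event, TranspositionEpoch):
        moves: list[_Copy] = []
        for chrom in list(state):
            stay: list[_Copy] = []
            for g in state[chrom]:
                if rng.random() < event.probability:
                    moves.append(g)
                else:
                    stay.append(g)
            state[chrom] = stay
        chroms = sorted(state)
        for g in moves:
            target = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(len(state[target]) + 1))
            if rng.random() < 0.5:
                g.strand = "+" if g.strand == "-" else "-"
            state[target].insert(pos, g)
        for chrom in list(state):
            if not state[chrom]:
                del state[chrom]
    else:  # pragma: no cover - exhaustive over Event
        raise TypeError(f"unknown event {event!r}")


# ---------------------------------------------------------------------------
# output container

@dataclass
class SimulatedHistory:
    """Two extant genomes with complete gene genealogy.

    ``lineage_map`` sends every extant gene id to its ancestral gene and WGD
    copy path; ``labels`` holds, for every homologous pair (cross-genome and
    same-genome), the true relation and the ordinal divergence depth in
    epochs (larger = older divergence).
    """

    genome_a: list[GeneLocation]
    genome_b: list[GeneLocation]
    lineage_map: dict[str, tuple[str, tuple[tuple[int, int], ...]]]
    labels: dict[frozenset[str], tuple[str, int]]
    n_shared_epochs: int
    n_epochs: int
    event_log: list[tuple[str, int, str, int]]  # (lineage, epoch, event kind, genes after)

    def genome(self, which: str) -> list[GeneLocation]:
        if which == "A":
            return self.genome_a
        if which == "B":
            return self.genome_b
        raise KeyError(which)

    def relation(self, gene_1: str, gene_2: str) -> tuple[str, int] | None:
        """(relation, depth) for a homologous pair, else None."""
        return self.labels.get(frozenset((gene_1, gene_2)))

    def true_ortholog_ids(self, gene: str) -> set[str]:
        out = set()
        for pair, (rel, _depth) in self.labels.items():
            if rel == ORTHOLOG and gene in pair:
                out |= pair - {gene}
        return out


def _materialize(state: _State, lineage: str) -> tuple[list[GeneLocation], dict]:
    locations: list[GeneLocation] = []
    lineage_map: dict[str, tuple[str, tuple[tuple[int, int], ...]]] = {}
    counter = 0
    for chrom in sorted(state):
        for rank, g in enumerate(state[chrom]):
            gene_id = f"{lineage}:{g.ancestral}:{counter}"
            counter += 1
            start = rank * _GENE_STEP + 1
            locations.append(
                GeneLocation(gene_id, chrom, start, start + _GENE_SPAN - 1,
                             g.strand, rank)
            )
            lineage_map[gene_id] = (g.ancestral, g.path)
    return locations, lineage_map


def _divergence_depth(
    path_1: tuple[tuple[int, int], ...],
    path_2: tuple[tuple[int, int], ...],
    cross: bool,
    split_epoch: int,
    total_epochs: int,
) -> tuple[str, int]:
    """Relation and depth from two copy paths of the same ancestral gene."""
    div_epoch = None
    for (e1, k1), (e2, k2) in zip(path_1, path_2):
        if e1 != e2:  # lineage-specific WGDs at different epochs
            div_epoch = min(e1, e2)
            break
        if k1 != k2:
            div_epoch = e1
            break
    if div_epoch is None and len(path_1) != len(path_2):
        longer = path_1 if len(path_1) > len(path_2) else path_2
        div_epoch = longer[min(len(path_1), len(path_2))][0]
    if cross:
        pre_1 = tuple(p for p in path_1 if p[0] <= split_epoch)
        pre_2 = tuple(p for p in path_2 if p[0] <= split_epoch)
        if pre_1 == pre_2:
            # diverged at the lineage split (or later duplications do not
            # matter: the pair's MRCA copy is the split-time copy)
            div_epoch = split_epoch if div_epoch is None else min(div_epoch, split_epoch)
            relation = ORTHOLOG if div_epoch == split_epoch else PARALOG
            return relation, total_epochs + 1 - div_epoch
        # diverged at a shared WGD
        for (e1, k1), (e2, k2) in zip(pre_1, pre_2):
            if k1 != k2:
                return PARALOG, total_epochs + 1 - e1
        longer = pre_1 if len(pre_1) > len(pre_2) else pre_2
        return PARALOG, total_epochs + 1 - longer[min(len(pre_1), len(pre_2))][0]
    # same genome: two distinct copies always diverged at some WGD
    if div_epoch is None:
        raise SimulationError("distinct same-genome copies with identical paths")
    return PARALOG, total_epochs + 1 - div_epoch


def simulate_history(
    ancestral: AncestralGenome, schedule: EventSchedule
) -> SimulatedHistory:
    """Evolve *ancestral* through *schedule* and return the labelled result.

    Epochs are numbered globally: shared events 1..S, the lineage split S+1,
    and the i-th event of either lineage S+1+i.  The divergence depth of a
    pair is ``total_epochs + 1 − divergence_epoch``, so orthologs (which
    diverged at the split) are always shallower than WGD1 paralogs.
    """
    ss = np.random.SeedSequence(schedule.seed)
    rng_shared, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(3))

    state: _State = {
        chrom: [
            _Copy(g, ancestral.strands[g], ())
            for g in ancestral.genes_per_chromosome[chrom]
        ]
        for chrom in ancestral.chromosomes
    }

    event_log: list[tuple[str, int, str, int]] = []

    def run(
        st: _State, events: Iterable[Event], rng: np.random.Generator,
        lineage: str, epoch_offset: int,
    ) -> int:
        epoch = epoch_offset
        for event in events:
            epoch += 1
            _apply_event(st, event, epoch, rng, lineage)
            event_log.append(
                (lineage, epoch, type(event).__name__,
                 sum(len(v) for v in st.values()))
            )
        return epoch

    n_shared = run(state, schedule.shared, rng_shared, "shared", 0)
    split_epoch = n_shared + 1
    event_log.append(("shared", split_epoch, "Split",
                      sum(len(v) for v in state.values())))

    state_a = _copy.deepcopy(state)
    state_b = _copy.deepcopy(state)
    end_a = run(state_a, schedule.lineage_a, rng_a, "A", split_epoch)
    end_b = run(state_b, schedule.lineage_b, rng_b, "B", split_epoch)
    total_epochs = max(end_a, end_b)

    genome_a, map_a = _materialize(state_a, "A")
    genome_b, map_b = _materialize(state_b, "B")
    lineage_map = {**map_a, **map_b}

    # group extant genes by ancestral gene
    by_anc: dict[str, tuple[list[str], list[str]]] = {}
    for gid, (anc, _path) in map_a.items():
        by_anc.setdefault(anc, ([], []))[0].append(gid)
    for gid, (anc, _path) in map_b.items():
        by_anc.setdefault(anc, ([], []))[1].append(gid)

    labels: dict[frozenset[str], tuple[str, int]] = {}
    for anc, (in_a, in_b) in by_anc.items():
        for g1 in in_a:
            for g2 in in_b:
                labels[frozenset((g1, g2))] = _divergence_depth(
                    lineage_map[g1][1], lineage_map[g2][1],
                    cross=True, split_epoch=split_epoch,
                    total_epochs=total_epochs,
                )
        for genes in (in_a, in_b):
            for i, g1 in enumerate(genes):
                for g2 in genes[i + 1:]:
                    labels[frozenset((g1, g2))] = _divergence_depth(
                        lineage_map[g1][1], lineage_map[g2][1],
                        cross=False, split_epoch=split_epoch,
                        total_epochs=total_epochs,
                    )

    return SimulatedHistory(
        genome_a=genome_a,
        genome_b=genome_b,
        lineage_map=lineage_map,
        labels=labels,
        n_shared_epochs=n_shared,
        n_epochs=total_epochs,
        event_log=event_log,
    )


# ---------------------------------------------------------------------------
# descent bookkeeping helpers

def wgd1_copy_groups(
    history: SimulatedHistory, genome: str = "B"
) -> dict[int, frozenset[str]]:
    """Group a genome's chromosomes by the WGD1 copy most of their genes carry.

    "WGD1" here is the first shared (pre-split) WGD in the schedule.  After
    fusions a chromosome can carry genes of mixed descent; it is assigned to
    the copy index of the majority of its genes (ties to the lower index).
    Chromosomes whose genes carry no shared-WGD entry are skipped.
    """
    first_shared_epoch = None
    for _gid, (_anc, path) in history.lineage_map.items():
        for epoch, _k in path:
            if epoch <= history.n_shared_epochs:
                first_shared_epoch = (
                    epoch if first_shared_epoch is None else min(first_shared_epoch, epoch)
                )
    if first_shared_epoch is None:
        return {}
    votes: dict[str, dict[int, int]] = {}
    for loc in history.genome(genome):
        _anc, path = history.lineage_map[loc.gene_id]
        copy = next(
            (k for epoch, k in path if epoch == first_shared_epoch), None
        )
        if copy is None:
            continue
        votes.setdefault(loc.chromosome, {}).setdefault(copy, 0)
        votes[loc.chromosome][copy] += 1
    groups: dict[int, set[str]] = {}
    for chrom, tally in votes.items():
        winner = min(sorted(tally), key=lambda k: (-tally[k], k))
        groups.setdefault(winner, set()).add(chrom)
    return {k: frozenset(v) for k, v in groups.items()}


# ---------------------------------------------------------------------------
# score-space similarity model

def _default_evalue(bit_score: float) -> float:
    # E ~ K * 2^-S with a database-size-like constant; strictly decreasing.
    return 1e9 * math.pow(2.0, -bit_score)


@dataclass(frozen=True)
class SimilarityModel:
    """Bit-score model for homolog similarity: base − decay·depth + noise."""

    base_score: float = 200.0
    decay_per_epoch: float = 10.0
    noise_sd: float = 0.0
    significance_floor: float = 40.0
    evalue_map: Callable[[float], float] = _default_evalue


def emit_hit_table(
    history: SimulatedHistory,
    model: SimilarityModel,
    seed: int,
    mode: str = "cross",
) -> list[HitRecord]:
    """Emit noisy BLAST-like hits for homologous pairs.

    ``mode='cross'`` emits both directions A-query->B-subject is the
    canonical direction used downstream; ``mode='within_a'`` /
    ``'within_b'`` emit same-genome paralog hits (both directions, no
    self-hits are fabricated beyond the trivial identity hit, which IS
    emitted at the base score so that self-hit exclusion is exercised
    downstream).  Hit noise is seeded independently of the history so the
    same history can be re-scored.
    """
    rng = np.random.default_rng(seed)
    a_ids = {g.gene_id for g in history.genome_a}
    b_ids = {g.gene_id for g in history.genome_b}

    def emit_pair(query: str, subject: str, depth: int, out: list[HitRecord]) -> None:
        score = (
            model.base_score
            - model.decay_per_epoch * depth
            + (rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0)
        )
        if score < model.significance_floor:
            return
        out.append(
            HitRecord(
                query_protein=query, subject_protein=subject,
                bit_score=round(float(score), 4),
                e_value=model.evalue_map(float(score)),
                query_gene=query, subject_gene=subject,
            )
        )

    records: list[HitRecord] = []
    if mode == "cross":
        pairs = sorted(
            (tuple(sorted(p)), d)
            for p, (_rel, d) in history.labels.items()
            if len(p & a_ids) == 1 and len(p & b_ids) == 1
        )
        for (g1, g2), depth in pairs:
            query, subject = (g1, g2) if g1 in a_ids else (g2, g1)
            emit_pair(query, subject, depth, records)
    elif mode in ("within_a", "within_b"):
        ids = a_ids if mode == "within_a" else b_ids
        genome = history.genome_a if mode == "within_a" else history.genome_b
        pairs = sorted(
            (tuple(sorted(p)), d)
            for p, (_rel, d) in history.labels.items()
            if p <= ids
        )
        for (g1, g2), depth in pairs:
            emit_pair(g1, g2, depth, records)
            emit_pair(g2, g1, depth, records)
        for g in sorted(x.gene_id for x in genome):
            emit_pair(g, g, 0, records)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return records
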