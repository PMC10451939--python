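"""Gene-loss scenarios behind "solo" genes, and the ortholog-marker bias.

When a query-genome (agnathan) gene has exactly one significant subject
(human) match, that single survivor arose through one of three loss
histories relative to the two vertebrate WGDs:

* scenario ``a`` — one WGD1 copy was lost in the shared ancestor before the
  lineage split, and one of the two WGD2 duplicates of the survivor was
  lost later: the surviving human gene *must* be the ortholog;
* scenario ``b`` — both losses happened in the gnathostome lineage, one
  before WGD2 and one after: the survivor is the ortholog with probability
  one half;
* scenario ``c`` — three gnathostome losses after WGD2 removed three of the
  four duplicates: again probability one half, but requiring one more loss
  (hence rarer whenever per-event loss probability is below one).

Averaged over scenarios, solo genes are therefore biased toward being true
orthologs — which is what licenses using them as markers for chromosome
correspondence.  ``ortholog_probability`` computes the per-scenario value
by exhaustive enumeration (exact rationals); ``simulate_scenario`` checks
it by Monte Carlo; ``simulate_solo_bias`` demonstrates the bias on full
simulated genomes run through the actual best-hit classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import sqrt

import numpy as np

from . import simulate as sim
from .classify import summarize_hits

__all__ = [
    "LossEvent",
    "LossScenario",
    "ScenarioOutcome",
    "ortholog_probability",
    "scenario_weight",
    "simulate_scenario",
    "SoloBiasResult",
    "simulate_solo_bias",
]


@dataclass(frozen=True)
class LossEvent:
    """One gene-copy loss, placed on the species tree and relative to WGD2."""

    lineage: str  # "shared" | "gnathostome"
    timing: str   # "post-WGD1" (before WGD2) | "post-WGD2"

    def __post_init__(self) -> None:
        if self.lineage not in ("shared", "gnathostome"):
            raise ValueError(f"bad lineage {self.lineage!r}")
        if self.timing not in ("post-WGD1", "post-WGD2"):
            raise ValueError(f"bad timing {self.timing!r}")
        if self.lineage == "shared" and self.timing == "post-WGD2":
            raise ValueError("shared losses predate WGD2")


_CANONICAL = {
    "a": (LossEvent("shared", "post-WGD1"), LossEvent("gnathostome", "post-WGD2")),
    "b": (LossEvent("gnathostome", "post-WGD1"), LossEvent("gnathostome", "post-WGD2")),
    "c": (LossEvent("gnathostome", "post-WGD2"),) * 3,
}


@dataclass(frozen=True)
class LossScenario:
    """A named loss history leaving exactly one human gene."""

    scenario_id: str
    losses: tuple[LossEvent, ...]

    @classmethod
    def from_id(cls, scenario_id: str) -> "LossScenario":
        if scenario_id not in _CANONICAL:
            raise ValueError(f"unknown scenario {scenario_id!r} (want a, b or c)")
        return cls(scenario_id, _CANONICAL[scenario_id])

    def __post_init__(self) -> None:
        if self.scenario_id in _CANONICAL and self.losses != _CANONICAL[self.scenario_id]:
            raise ValueError(
                f"losses inconsistent with scenario {self.scenario_id!r}"
            )

    @property
    def n_losses(self) -> int:
        return len(self.losses)


@dataclass(frozen=True)
class ScenarioOutcome:
    """Exact probability that the surviving human gene is the ortholog."""

    probability: Fraction
    n_losses: int
    n_assignments: int  # enumerated copy-loss assignments after conditioning


def _enumerate(scenario: LossScenario):
    """Yield (weight, survivor_wgd1_copy) over uniform copy-loss assignments.

    The observed query (lamprey) gene descends, w.l.o.g., from WGD1 copy 0;
    copy symmetry makes the answer independent of that choice.  Branches are
    discarded (conditioned away) when the query's copy is struck by a shared
    loss — no lamprey survivor — or when the human survivor count is not 1.
    """
    shared = [e for e in scenario.losses if e.lineage == "shared"]
    gn_pre = [
        e for e in scenario.losses
        if e.lineage == "gnathostome" and e.timing == "post-WGD1"
    ]
    gn_post = [
        e for e in scenario.losses
        if e.lineage == "gnathostome" and e.timing == "post-WGD2"
    ]

    def recurse(copies: list[int], losses: list[LossEvent], weight: Fraction):
        """Enumerate uniform strike choices for one epoch's losses."""
        if not losses:
            yield weight, copies
            return
        if not copies:
            return
        n = len(copies)
        for i in range(n):
            struck = copies[:i] + copies[i + 1:]
            yield from recurse(struck, losses[1:], weight * Fraction(1, n))

    query_copy = 0
    for w1, after_shared in recurse([0, 1], shared, Fraction(1)):
        if query_copy not in after_shared:
            continue  # no lamprey survivor: condition away
        for w2, after_pre in recurse(list(after_shared), gn_pre, w1):
            duplicated = [c for c in after_pre for _ in range(2)]  # WGD2
            for w3, survivors in recurse(duplicated, gn_post, w2):
                if len(survivors) != 1:
                    continue
                yield w3, survivors[0]


def ortholog_probability(scenario: LossScenario | str) -> ScenarioOutcome:
    """Exact P(single human survivor is the query's ortholog), by enumeration."""
    if isinstance(scenario, str):
        scenario = LossScenario.from_id(scenario)
    total = Fraction(0)
    ortholog = Fraction(0)
    n_assignments = 0
    for weight, survivor_copy in _enumerate(scenario):
        n_assignments += 1
        total += weight
        if survivor_copy == 0:
            ortholog += weight
    if total == 0:
        raise ValueError(
            f"scenario {scenario.scenario_id!r} never leaves one human survivor"
        )
    return ScenarioOutcome(
        probability=ortholog / total,
        n_losses=scenario.n_losses,
        n_assignments=n_assignments,
    )


def scenario_weight(scenario: LossScenario | str, loss_probability: float) -> float:
    """Relative weight p^(number of required losses).

    With per-event loss probability p < 1, the three-loss scenario ``c`` is
    p times rarer than the two-loss scenarios ``a`` and ``b``.
    """
    if isinstance(scenario, str):
        scenario = LossScenario.from_id(scenario)
    if not 0 < loss_probability < 1:
        raise ValueError("loss probability must be in (0, 1)")
    return loss_probability ** scenario.n_losses


def simulate_scenario(
    scenario: LossScenario | str, n_trials: int, seed: int
) -> tuple[float, int]:
    """Monte-Carlo estimate of :func:`ortholog_probability`.

    Returns (empirical ortholog fraction, number of accepted trials); trials
    failing the conditioning (no lamprey survivor / human survivor count
    not 1) are rejected.
    """
    if isinstance(scenario, str):
        scenario = LossScenario.from_id(scenario)
    rng = np.random.default_rng(seed)
    shared = [e for e in scenario.losses if e.lineage == "shared"]
    gn_pre = [
        e for e in scenario.losses
        if e.lineage == "gnathostome" and e.timing == "post-WGD1"
    ]
    gn_post = [
        e for e in scenario.losses
        if e.lineage == "gnathostome" and e.timing == "post-WGD2"
    ]
    hits = 0
    accepted = 0
    for _ in range(n_trials):
        copies = [0, 1]
        ok = True
        for _e in shared:
            copies.pop(rng.integers(len(copies)))
            if 0 not in copies:
                ok = False
                break
        if not ok:
            continue
        for _e in gn_pre:
            if not copies:
                ok = False
                break
            copies.pop(rng.integers(len(copies)))
        if not ok:
            continue
        human = [c for c in copies for _ in range(2)]
        for _e in gn_post:
            if not human:
                break
            human.pop(rng.integers(len(human)))
        if len(human) != 1:
            continue
        accepted += 1
        if human[0] == 0:
            hits += 1
    return (hits / accepted if accepted else float("nan")), accepted


# ---------------------------------------------------------------------------
# whole-genome demonstration of the solo bias

@dataclass(frozen=True)
class SoloBiasResult:
    """Empirical ortholog fractions for solo vs non-solo queries.

    For a solo query the fraction concerns its unique match; for non-solo
    queries each listed best match counts separately (a single match of a
    multi-match query carries no information about which one is the
    ortholog, which is precisely why solo genes are the useful markers).
    Standard errors are binomial.
    """

    solo_fraction: float
    solo_n: int
    nonsolo_fraction: float
    nonsolo_n: int

    @property
    def solo_se(self) -> float:
        f, n = self.solo_fraction, self.solo_n
        return sqrt(f * (1 - f) / n) if n else float("nan")

    @property
    def nonsolo_se(self) -> float:
        f, n = self.nonsolo_fraction, self.nonsolo_n
        return sqrt(f * (1 - f) / n) if n else float("nan")

    @property
    def enrichment_z(self) -> float:
        """(solo − non-solo) in units of the combined standard error."""
        se = sqrt(self.solo_se ** 2 + self.nonsolo_se ** 2)
        return (self.solo_fraction - self.nonsolo_fraction) / se if se else float("nan")


def simulate_solo_bias(
    retention: float,
    n_genes: int,
    seed: int,
    decay_per_epoch: float = 10.0,
) -> SoloBiasResult:
    """Simulate WGD1 + split + WGD2 with i.i.d. losses and measure the bias.

    The shared lineage undergoes WGD1 then a loss epoch; the query lineage a
    loss epoch; the subject lineage a loss epoch, WGD2, and another loss
    epoch — so scenario-``a``, ``b`` and ``c`` type histories all occur.
    Hits are noise-free (score strictly decreasing in divergence depth) and
    classified by the production classifier.
    """
    if not 0 < retention <= 1:
        raise ValueError("retention must be in (0, 1]")
    ancestral = sim.uniform_ancestral_genome(1, n_genes)
    loss = sim.LossEpoch(retention)
    schedule = sim.EventSchedule(
        shared=(sim.WGD(2), loss),
        lineage_a=(loss,),
        lineage_b=(loss, sim.WGD(2), loss),
        seed=seed,
    )
    history = sim.simulate_history(ancestral, schedule)
    model = sim.SimilarityModel(decay_per_epoch=decay_per_epoch, noise_sd=0.0)
    hits = sim.emit_hit_table(history, model, seed=seed + 1)
    summaries = summarize_hits(hits)

    solo_orth = solo_n = 0
    pair_orth = pair_n = 0
    for summ in summaries:
        if not summ.best_subjects:
            continue
        if summ.is_solo:
            solo_n += 1
            rel = history.relation(summ.query_gene, summ.best_subjects[0][0])
            if rel is not None and rel[0] == sim.ORTHOLOG:
                solo_orth += 1
        else:
            for subject, _score, _e in summ.best_subjects:
                pair_n += 1
                rel = history.relation(summ.query_gene, subject)
                if rel is not None and rel[0] == sim.ORTHOLOG:
                    pair_orth += 1
    return SoloBiasResult(
        solo_fraction=solo_orth / solo_n if solo_n else float("nan"),
        solo_n=solo_n,
        nonsolo_fraction=pair_orth / pair_n if pair_n else float("nan"),
        nonsolo_n=pair_n,
    )
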