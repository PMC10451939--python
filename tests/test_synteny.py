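"""Neighborhood extraction, best-hit mapping, congruence and conserved blocks."""

from __future__ import annotations

import itertools

import pytest

import ohnomap as om
from ohnomap.synteny import MappedGene, NeighborhoodMapping

from conftest import make_hit, make_locations


def mapping_from_order(
    genes_in_order: list[tuple[str, str | None, bool | None]],
    chromosome: str = "q",
    genome: str = "",
) -> NeighborhoodMapping:
    """Build a neighborhood whose genes map to given subjects/orientations."""
    locs = make_locations({chromosome: [g for g, _s, _o in genes_in_order]})
    nbhd = om.Neighborhood(
        anchor=genes_in_order[0][0], flank=tuple(locs), genome=genome
    )
    entries = tuple(
        MappedGene(g, "+", subj, "S" if subj else None, ori)
        for (g, subj, ori) in genes_in_order
    )
    return NeighborhoodMapping(nbhd, entries)


class TestExtractNeighborhood:
    def test_edge_truncation_is_flagged(self):
        locs = make_locations({"c": [f"g{i}" for i in range(6)]})
        nbhd = om.extract_neighborhood(locs, "g2", half_width=5)
        assert [g.gene_id for g in nbhd.flank] == [f"g{i}" for i in range(6)]
        assert nbhd.truncated_left and nbhd.truncated_right

    def test_single_gene_chromosome_is_anchor_alone(self):
        locs = make_locations({"c": ["only"]})
        nbhd = om.extract_neighborhood(locs, "only")
        assert [g.gene_id for g in nbhd.flank] == ["only"]

    def test_unknown_anchor_raises(self):
        with pytest.raises(KeyError, match="ghost"):
            om.extract_neighborhood(make_locations({"c": ["g"]}), "ghost")

    @pytest.mark.parametrize("anchor_idx", [0, 3, 10, 19])
    def test_matches_naive_rank_window(self, anchor_idx):
        genes = [f"g{i}" for i in range(20)]
        locs = make_locations({"c": genes, "other": ["x1", "x2"]})
        nbhd = om.extract_neighborhood(locs, genes[anchor_idx], half_width=5)
        lo, hi = max(0, anchor_idx - 5), min(len(genes), anchor_idx + 6)
        assert [g.gene_id for g in nbhd.flank] == genes[lo:hi]


class TestMapNeighborhood:
    def test_gene_without_hit_is_marked_no_hit(self):
        locs = make_locations({"c": ["a", "b"]})
        subj = make_locations({"s": ["t1"]})
        nbhd = om.extract_neighborhood(locs, "a")
        mapping = om.map_neighborhood(nbhd, [make_hit("a", "t1", 90.0)], subj)
        by_gene = {e.gene_id: e for e in mapping.entries}
        assert by_gene["a"].subject_gene == "t1"
        assert not by_gene["b"].has_hit

    def test_orientation_relative_to_subject_strand(self):
        locs = make_locations({"c": ["a"]}, strand="-")
        subj = make_locations({"s": ["t_plus"]}, strand="+")
        nbhd = om.extract_neighborhood(locs, "a")
        mapping = om.map_neighborhood(nbhd, [make_hit("a", "t_plus", 90.0)], subj)
        assert mapping.entries[0].same_orientation is False

    def test_simulated_wgd_neighborhood_maps_to_truth_orthologs(self):
        """No losses, no transposition, no noise: every flank gene's best
        subject is its true ortholog."""
        anc = om.uniform_ancestral_genome(1, 12)
        hist = om.simulate_history(
            anc, om.EventSchedule(shared=(om.WGD(2),), seed=4)
        )
        hits = om.emit_hit_table(hist, om.SimilarityModel(noise_sd=0.0), seed=0)
        anchor = hist.genome_a[5].gene_id
        nbhd = om.extract_neighborhood(hist.genome_a, anchor, genome="A")
        mapping = om.map_neighborhood(nbhd, hits, hist.genome_b)
        for entry in mapping.entries:
            assert entry.has_hit
            assert entry.subject_gene in hist.true_ortholog_ids(entry.gene_id)


def brute_force_abs_tau(order_1: list[int], order_2: list[int]) -> float:
    pos2 = {f: i for i, f in enumerate(order_2)}
    concordant = discordant = 0
    for (i, a), (j, b) in itertools.combinations(enumerate(order_1), 2):
        if (pos2[a] - pos2[b]) * (i - j) > 0:
            concordant += 1
        else:
            discordant += 1
    n = len(order_1)
    return abs(concordant - discordant) / (n * (n - 1) / 2)


class TestCongruence:
    def test_identical_orderings_score_one(self):
        genes = [(f"g{i}", f"F{i}", True) for i in range(7)]
        m1 = mapping_from_order(genes, "c1", genome="G1")
        m2 = mapping_from_order(
            [(f"h{i}", f"F{i}", True) for i in range(7)], "c2", genome="G2"
        )
        result = om.congruence_scores(m1, m2)
        assert (result.shared, result.order_score, result.orientation_score) == (
            7, 1.0, 1.0
        )

    def test_exact_reversal_still_scores_one(self):
        m1 = mapping_from_order(
            [(f"g{i}", f"F{i}", True) for i in range(7)], "c1", "G1"
        )
        m2 = mapping_from_order(
            [(f"h{i}", f"F{6 - i}", False) for i in range(7)], "c2", "G2"
        )
        result = om.congruence_scores(m1, m2)
        assert result.order_score == 1.0
        assert result.reversed_order
        # a clean inversion flips every relative orientation together
        assert result.orientation_score == 1.0

    def test_symmetry_in_arguments(self):
        m1 = mapping_from_order(
            [("g0", "FA", True), ("g1", "FB", False), ("g2", "FC", True)], "c1", "G1"
        )
        m2 = mapping_from_order(
            [("h0", "FB", True), ("h1", "FA", True), ("h2", "FC", True)], "c2", "G2"
        )
        r12 = om.congruence_scores(m1, m2)
        r21 = om.congruence_scores(m2, m1)
        assert (r12.shared, r12.order_score, r12.orientation_score) == (
            r21.shared, r21.order_score, r21.orientation_score
        )

    def test_fewer_than_two_shared_families_reports_undefined_order(self):
        m1 = mapping_from_order([("g0", "FA", True)], "c1", "G1")
        m2 = mapping_from_order([("h0", "FA", True)], "c2", "G2")
        result = om.congruence_scores(m1, m2)
        assert result.shared == 1 and result.order_score is None

    @pytest.mark.parametrize("perm_index", [0, 99, 260, 475, 719])
    def test_order_score_matches_brute_force_kendall(self, perm_index):
        perms = list(itertools.permutations(range(6)))
        perm = perms[perm_index]
        m1 = mapping_from_order(
            [(f"g{i}", f"F{i}", True) for i in range(6)], "c1", "G1"
        )
        m2 = mapping_from_order(
            [(f"h{i}", f"F{perm[i]}", True) for i in range(6)], "c2", "G2"
        )
        result = om.congruence_scores(m1, m2)
        expected = brute_force_abs_tau(list(range(6)), list(perm))
        assert result.order_score == pytest.approx(expected)

    def test_all_720_permutations_match_brute_force(self):
        m1_order = list(range(6))
        for perm in itertools.permutations(range(6)):
            m1 = mapping_from_order(
                [(f"g{i}", f"F{i}", True) for i in range(6)], "c1", "G1"
            )
            m2 = mapping_from_order(
                [(f"h{i}", f"F{perm[i]}", True) for i in range(6)], "c2", "G2"
            )
            result = om.congruence_scores(m1, m2)
            assert result.order_score == pytest.approx(
                brute_force_abs_tau(m1_order, list(perm))
            )


SEVEN = ("GRID", "CCSER", "MMRN", "SNC", "GLUD", "SHLD", "GPRIN")


class TestConservedBlocks:
    def test_seven_gene_ancestral_block_is_reported(self):
        """A lamprey-like neighborhood carries the full seven-family run;
        two human neighborhoods carry partial runs around their anchors."""
        sequences = {
            "lamprey_chr8": list(SEVEN),
            "human_SNCA": ["GRID", "CCSER", "MMRN", "SNC", None, "OTHER1"],
            "human_SNCG": ["OTHER2", None, "SNC", "GLUD", "SHLD", "GPRIN"],
        }
        blocks = om.find_conserved_blocks(sequences, min_members=1, min_length=2)
        full = [b for b in blocks if b.length == 7]
        assert len(full) == 1
        assert full[0].families in (SEVEN, SEVEN[::-1])
        assert "lamprey_chr8" in full[0].members
        shared_with_snca = [
            b for b in blocks if b.members >= {"lamprey_chr8", "human_SNCA"}
        ]
        assert any(b.length == 4 for b in shared_with_snca)

    def test_no_shared_families_no_blocks(self):
        sequences = {"n1": ["A", "B", "C"], "n2": ["X", "Y", "Z"]}
        assert om.find_conserved_blocks(sequences, min_members=2) == set()

    def test_reversed_occurrence_counts_as_member(self):
        sequences = {"fwd": ["A", "B", "C"], "rev": ["C", "B", "A"]}
        blocks = om.find_conserved_blocks(sequences, min_members=2, min_length=3)
        assert len(blocks) == 1
        (block,) = blocks
        assert block.members == {"fwd", "rev"}

    def test_gap_budget_limits_unlabelled_interruptions(self):
        sequences = {
            "tight": ["A", "B"],
            "gapped": ["A", None, None, "B"],
            "too_gapped": ["A", None, None, None, "B"],
        }
        blocks = om.find_conserved_blocks(
            sequences, min_members=2, min_length=2, gap_budget=2
        )
        (block,) = blocks
        assert block.members == {"tight", "gapped"}

    def test_small_random_instances_match_exhaustive_enumeration(self, rng):
        labels = ["A", "B", "C", "D"]
        for trial in range(25):
            sequences = {}
            for nid in range(3):
                seq = [
                    (str(rng.choice(labels)) if rng.random() < 0.7 else None)
                    for _ in range(int(rng.integers(3, 9)))
                ]
                sequences[f"n{nid}"] = seq
            got = {
                (b.families, b.members)
                for b in om.find_conserved_blocks(
                    sequences, min_members=2, min_length=2, gap_budget=1
                )
            }
            expected = exhaustive_blocks(sequences, 2, 2, 1)
            assert got == expected, f"trial {trial}: {sequences}"

    def test_blocks_are_maximal(self, rng):
        for _ in range(10):
            sequences = {
                f"n{i}": [
                    str(rng.choice(["A", "B", "C"])) if rng.random() < 0.8 else None
                    for _ in range(8)
                ]
                for i in range(3)
            }
            blocks = om.find_conserved_blocks(sequences, min_members=2)
            for b1 in blocks:
                for b2 in blocks:
                    if b1 is b2 or b2.length <= b1.length:
                        continue
                    contained = any(
                        b2.families[i:i + b1.length] in (b1.families, b1.families[::-1])
                        for i in range(b2.length - b1.length + 1)
                    )
                    assert not (contained and b2.members >= b1.members)


def exhaustive_blocks(sequences, min_members, min_length, gap_budget):
    """Independent oracle: enumerate every label tuple and test containment
    by scanning all position subsequences."""
    alphabet = sorted(
        {lab for seq in sequences.values() for lab in seq if lab is not None}
    )

    def contains(seq, pattern):
        for target in {pattern, pattern[::-1]}:
            k = len(target)
            for positions in itertools.combinations(range(len(seq)), k):
                if tuple(seq[p] for p in positions) != target:
                    continue
                ok = True
                for p, q in zip(positions, positions[1:]):
                    between = seq[p + 1:q]
                    if any(x is not None for x in between) or len(between) > gap_budget:
                        ok = False
                        break
                if ok:
                    return True
        return False

    found = {}
    max_len = max(len(s) for s in sequences.values())
    for k in range(min_length, max_len + 1):
        for pattern in itertools.product(alphabet, repeat=k):
            canon = min(pattern, pattern[::-1])
            if canon in found:
                continue
            members = frozenset(
                nid for nid, seq in sequences.items() if contains(seq, canon)
            )
            if len(members) >= min_members:
                found[canon] = members

    maximal = set()
    for pattern, members in found.items():
        dominated = False
        for other, other_members in found.items():
            if len(other) <= len(pattern) or not (other_members >= members):
                continue
            for cand in (pattern, pattern[::-1]):
                if any(
                    other[i:i + len(cand)] == cand
                    for i in range(len(other) - len(cand) + 1)
                ):
                    dominated = True
                    break
            if dominated:
                break
        if not dominated:
            maximal.add((pattern, members))
    return maximal


def test_loss_free_simulation_gives_perfect_order_congruence():
    """Against its WGD sister region, an undisturbed neighborhood keeps
    order score 1 and full orientation consistency."""
    anc = om.uniform_ancestral_genome(1, 12)
    hist = om.simulate_history(anc, om.EventSchedule(shared=(om.WGD(2),), seed=4))
    hits = om.emit_hit_table(hist, om.SimilarityModel(noise_sd=0.0), seed=0)
    anchor_a = hist.genome_a[5].gene_id
    nbhd_a = om.extract_neighborhood(hist.genome_a, anchor_a, genome="A")
    mapped = om.map_neighborhood(nbhd_a, hits, hist.genome_b)
    anchor_b = mapped.entries[nbhd_a.flank.index(
        next(g for g in nbhd_a.flank if g.gene_id == anchor_a)
    )].subject_gene
    nbhd_b = om.extract_neighborhood(hist.genome_b, anchor_b, genome="B")
    reference = om.identity_mapping(nbhd_b)
    result = om.congruence_scores(mapped, reference)
    assert result.shared == 11
    assert result.order_score == 1.0
    assert result.orientation_score == 1.0
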