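"""Pre-filter bank: local-alignment contract against a brute-force
Smith-Waterman oracle, the five filter predicates, the cascade tally and
filter-order invariance of the surviving set."""

import itertools

import numpy as np
import pytest

from rtchimera import fixtures as fx
from rtchimera.annotation_model import (
    load_annotation,
    load_genome,
    load_paralogs,
    reverse_complement,
)
from rtchimera.junction_db import (
    enumerate_candidate_pairs,
    enumerate_exon_combinations,
    dedupe_by_breakpoints,
    make_junction,
)
from rtchimera.prefilters import (
    GAP_EXTEND,
    GAP_OPEN,
    MATCH_SCORE,
    MISMATCH_SCORE,
    cross_similar_exons,
    exon_filter,
    flank_length_filter,
    is_paralog_pair,
    local_align,
    matches_some_exon,
    paralog_filter,
    run_prefilter_cascade,
    same_isoform_filter,
    similarity_filter,
    unique_exon_sequences,
    violates_same_isoform,
)

from conftest import make_junction_record


def sw_oracle(query, subject):
    """Brute-force affine-gap Smith-Waterman returning (identity, query_coverage)
    of one best local alignment. Independent of the production aligner."""
    n, m = len(query), len(subject)
    NEG = -10**9
    # H: match/mismatch state, E: gap in subject (consume query), F: gap in query
    H = np.full((n + 1, m + 1), NEG, float)
    E = np.full((n + 1, m + 1), NEG, float)
    F = np.full((n + 1, m + 1), NEG, float)
    H[0, :] = 0
    H[:, 0] = 0
    best, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH_SCORE if query[i - 1] == subject[j - 1] else MISMATCH_SCORE
            E[i, j] = max(H[i - 1, j] + GAP_OPEN, E[i - 1, j] + GAP_EXTEND)
            F[i, j] = max(H[i, j - 1] + GAP_OPEN, F[i, j - 1] + GAP_EXTEND)
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            if H[i, j] > best:
                best, best_ij = H[i, j], (i, j)
    if best <= 0:
        return 0.0, 0.0, 0.0
    # traceback
    i, j = best_ij
    matches = mismatches = gaps = qbases = 0
    state = "H"
    while i > 0 and j > 0 and not (state == "H" and H[i, j] == 0):
        if state == "H":
            s = MATCH_SCORE if query[i - 1] == subject[j - 1] else MISMATCH_SCORE
            if H[i, j] == H[i - 1, j - 1] + s:
                matches += query[i - 1] == subject[j - 1]
                mismatches += query[i - 1] != subject[j - 1]
                qbases += 1
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            gaps += 1
            qbases += 1
            if E[i, j] == H[i - 1, j] + GAP_OPEN:
                state = "H"
            i -= 1
        else:
            gaps += 1
            if F[i, j] == H[i, j - 1] + GAP_OPEN:
                state = "H"
            j -= 1
    cols = matches + mismatches + gaps
    return best, matches / cols, qbases / len(query)


RAND = np.random.default_rng(20240901)


def _rand_seq(n):
    return "".join(np.array(list("ACGT"))[RAND.integers(0, 4, n)])


class TestLocalAlign:
    def test_identical_sequences_full_identity_and_coverage(self):
        q = _rand_seq(40)
        s = local_align(q, q)
        assert s.identity == 1.0 and s.query_coverage == 1.0

    def test_half_containment_gives_half_coverage(self):
        q = _rand_seq(40)
        subject = q[:20] + _rand_seq(60)
        s = local_align(q, subject)
        oracle_score, oid, ocov = sw_oracle(q, subject)
        # the embedded 20-mer dominates: coverage near 0.5, as the oracle agrees
        assert s.query_coverage == pytest.approx(ocov)
        assert s.identity == pytest.approx(oid)

    @pytest.mark.parametrize("qlen,slen", [(12, 18), (20, 30), (40, 60)])
    def test_score_matches_brute_force_oracle(self, qlen, slen):
        """The production aligner reaches the same optimal local score as an
        independent DP on random sequence pairs."""
        from rtchimera.prefilters import _ALIGNER

        for _ in range(15):
            q, s = _rand_seq(qlen), _rand_seq(slen)
            oracle_score, _, _ = sw_oracle(q, s)
            got = _ALIGNER.align(q, s).score if oracle_score > 0 else 0
            assert got == pytest.approx(oracle_score)

    def test_dissimilar_sequences_low_coverage(self):
        q, s = _rand_seq(40), _rand_seq(40)
        summary = local_align(q, s)
        assert summary.query_coverage < 0.9

    def test_empty_inputs_zero_summary(self):
        s = local_align("", "ACGT")
        assert s.identity == 0.0 and s.query_coverage == 0.0


class TestSimplePredicates:
    def test_paralog_pair_removed_nonparalog_kept(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("G1\tG2\n")
        rel = load_paralogs(str(p))
        assert is_paralog_pair("G1", "G2", rel)
        assert is_paralog_pair("G2", "G1", rel)
        assert not is_paralog_pair("G1", "G3", rel)

    def test_empty_relation_is_identity(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("")
        rel = load_paralogs(str(p))
        combos = ["c1", "c2"]  # paralog_filter only inspects gene ids

        class FakeGene:
            def __init__(self, gid):
                self.gene_id = gid

        class FakeCombo:
            five_gene = FakeGene("A")
            three_gene = FakeGene("B")

        assert len(paralog_filter([FakeCombo(), FakeCombo()], rel)) == 2

    def test_flank_boundary_at_exon_length_twenty(self, tmp_path):
        spec = fx.FixtureSpec(
            seed=7, chromosomes={"c": 6000},
            genes=[
                fx.GeneSpec("A", "A", "c", "+", ((1000, 1019), (1500, 1520))),
                fx.GeneSpec("B", "B", "c", "+", ((2000, 2020), (2500, 3500))),
            ],
        )
        world = fx.generate_world(spec, str(tmp_path))
        ann = load_annotation(world.gtf)
        combos = [
            c
            for f, t in enumerate_candidate_pairs(ann)
            for c in enumerate_exon_combinations(f, t)
        ]
        kept = flank_length_filter(combos, flank=20)
        # 2 donor exons x 2 acceptor exons; the 19-bp donor is excluded,
        # the 20-bp exons sit exactly on the boundary and survive
        assert len(combos) == 4 and len(kept) == 2
        assert {c.donor.length for c in kept} == {20}
        assert all(c.acceptor.length >= 20 for c in kept)


def _overlapping_gene_world(tmp_path, break_adjacency=False):
    """Gene ISO1 with two (or three) exons; gene ISO2's single exon shares
    coordinates with an ISO1 exon, mimicking overlapping gene annotations."""
    exons1 = ((1000, 1120), (1500, 1620), (2000, 2120))
    acceptor_exon = (2000, 2120) if break_adjacency else (1500, 1620)
    spec = fx.FixtureSpec(
        seed=8, chromosomes={"c": 6000},
        genes=[
            fx.GeneSpec("ISO1", "ISO1", "c", "+", exons1),
            fx.GeneSpec("ISO2", "ISO2", "c", "+", (acceptor_exon,)),
        ],
    )
    return fx.generate_world(spec, str(tmp_path))


class TestSameIsoform:
    def test_consecutive_shared_exons_discarded(self, tmp_path):
        world = _overlapping_gene_world(tmp_path)
        genome, ann = load_genome(world.fasta), load_annotation(world.gtf)
        combos = [
            c
            for f, t in enumerate_candidate_pairs(ann)
            for c in enumerate_exon_combinations(f, t)
        ]
        junctions = [make_junction(c, genome) for c in combos]
        target = [
            j for j in junctions
            if j.five_gene_id == "ISO1"
            and (j.donor_exon.start, j.acceptor_exon.start) == (1000, 1500)
        ]
        assert target and all(violates_same_isoform(j, ann) for j in target)

    def test_nonadjacent_shared_exon_kept(self, tmp_path):
        world = _overlapping_gene_world(tmp_path, break_adjacency=True)
        genome, ann = load_genome(world.fasta), load_annotation(world.gtf)
        combos = [
            c
            for f, t in enumerate_candidate_pairs(ann)
            for c in enumerate_exon_combinations(f, t)
        ]
        for c in combos:
            if (
                c.five_gene.gene_id == "ISO1"
                and (c.donor.start, c.acceptor.start) == (1000, 2000)
            ):
                j = make_junction(c, genome)
                assert not violates_same_isoform(j, ann)

    def test_non_overlapping_genes_kept(self, loaded):
        genome, ann, _ = loaded
        combos = [
            c
            for f, t in enumerate_candidate_pairs(ann)
            for c in enumerate_exon_combinations(f, t)
        ]
        junctions = [make_junction(c, genome) for c in combos]
        assert same_isoform_filter(junctions, ann) == junctions


class TestExonFilter:
    def test_verbatim_containment_discarded(self):
        j = make_junction_record(_rand_seq(40), "J1")
        host_exon = _rand_seq(30) + j.sequence + _rand_seq(30)
        assert matches_some_exon(j, [host_exon])

    def test_thirty_of_forty_bases_kept(self):
        j = make_junction_record(_rand_seq(40), "J1")
        host = _rand_seq(30) + j.sequence[:30] + _rand_seq(30)
        # 30/40 = 75% coverage < 90%
        assert not matches_some_exon(j, [host])

    def test_two_mismatches_full_length_discarded(self):
        seq = _rand_seq(40)
        j = make_junction_record(seq, "J1")
        mutated = list(seq)
        for pos in (7, 23):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        host = _rand_seq(25) + "".join(mutated) + _rand_seq(25)
        # 38/40 identity (95%) over full coverage -> discard
        assert matches_some_exon(j, [host])

    def test_reverse_complement_containment_discarded(self):
        j = make_junction_record(_rand_seq(40), "J1")
        host = _rand_seq(10) + reverse_complement(j.sequence) + _rand_seq(10)
        assert matches_some_exon(j, [host])

    def test_strict_thresholds_equal_substring_oracle(self):
        """With identity and coverage at 1.0 the filter discards exactly the
        junctions whose sequence is a substring of some exon."""
        exons = [_rand_seq(120) for _ in range(5)]
        junctions = [make_junction_record(_rand_seq(40), f"J{i}") for i in range(5)]
        junctions.append(make_junction_record(exons[2][40:80], "Jcontained"))
        survivors = exon_filter(junctions, exons, id_min=1.0, cov_min=1.0)
        oracle = [
            j for j in junctions
            if not any(
                j.sequence in e or reverse_complement(j.sequence) in e
                for e in exons
            )
        ]
        assert survivors == oracle


class TestSimilarityFilter:
    def test_duplicated_donor_exon_discarded(self, decoy_world):
        genome, ann = load_genome(decoy_world.fasta), load_annotation(decoy_world.gtf)
        combos = [
            c
            for f, t in enumerate_candidate_pairs(ann)
            for c in enumerate_exon_combinations(f, t)
            if f.gene_id == "SIM1"
        ]
        (combo,) = combos
        j = make_junction(combo, genome)
        assert cross_similar_exons(j, ann, genome)

    def test_unrelated_genes_kept(self, loaded):
        genome, ann, _ = loaded
        combos = [
            c
            for f, t in enumerate_candidate_pairs(ann)
            for c in enumerate_exon_combinations(f, t)
        ]
        junctions = [make_junction(c, genome) for c in combos]
        assert similarity_filter(junctions, ann, genome) == junctions

    def test_half_identity_kept(self, tmp_path):
        """A partner exon sharing only half its sequence stays below the
        70% coverage bound."""
        spec = fx.FixtureSpec(
            seed=12, chromosomes={"c": 6000},
            genes=[
                fx.GeneSpec("A", "A", "c", "+", ((1000, 1100),)),
                fx.GeneSpec("B", "B", "c", "+", ((3000, 3100),)),
            ],
        )
        world = fx.generate_world(spec, str(tmp_path))
        # copy only the second half of A's exon into B's exon tail
        seq = world.chrom_seqs["c"]
        patched = seq[:3050] + seq[1050:1100] + seq[3100:]
        from conftest import write_fasta

        fasta = write_fasta(tmp_path / "g2.fa", {"c": patched})
        genome, ann = load_genome(fasta), load_annotation(world.gtf)
        combos = [
            c
            for f, t in enumerate_candidate_pairs(ann)
            for c in enumerate_exon_combinations(f, t)
        ]
        (combo,) = combos
        j = make_junction(combo, genome)
        assert not cross_similar_exons(j, ann, genome)


class TestCascade:
    def test_one_discard_per_stage_on_decoy_world(self, decoy_world):
        genome = load_genome(decoy_world.fasta)
        ann = load_annotation(decoy_world.gtf)
        paralogs = load_paralogs(decoy_world.paralogs_tsv)
        combos = [
            c
            for f, t in enumerate_candidate_pairs(ann)
            for c in enumerate_exon_combinations(f, t)
        ]
        junctions, tally = run_prefilter_cascade(combos, ann, genome, paralogs)
        for stage in ("paralog", "flank_length", "same_isoform", "exon", "similarity"):
            assert tally.discarded(stage) == 1, stage
        retained = [r for _, _, r in tally.stages]
        discarded = [d for _, d, _ in tally.stages]
        # the retained cascade is consistent: each stage starts from the last
        for i in range(1, len(tally.stages)):
            if i != 2:  # stage 2 input is junctions (deduped), not combinations
                assert retained[i] == retained[i - 1] - discarded[i]

    def test_no_victims_all_stages_identity(self, loaded):
        genome, ann, paralogs = loaded
        combos = [
            c
            for f, t in enumerate_candidate_pairs(ann)
            for c in enumerate_exon_combinations(f, t)
        ]
        junctions, tally = run_prefilter_cascade(combos, ann, genome, paralogs)
        assert len(junctions) == 20
        assert all(d == 0 for _, d, _ in tally.stages)

    def test_surviving_set_invariant_under_filter_order(self, decoy_world):
        """Each filter is a pure predicate, so the final set does not depend on
        the order the junction-level filters are applied in."""
        genome = load_genome(decoy_world.fasta)
        ann = load_annotation(decoy_world.gtf)
        paralogs = load_paralogs(decoy_world.paralogs_tsv)
        combos = [
            c
            for f, t in enumerate_candidate_pairs(ann)
            for c in enumerate_exon_combinations(f, t)
        ]
        constructible = flank_length_filter(combos)
        junctions = dedupe_by_breakpoints(
            make_junction(c, genome) for c in constructible
        )
        exon_seqs = unique_exon_sequences(ann, genome)
        stages = {
            "paralog": lambda js: [
                j for j in js
                if not is_paralog_pair(j.five_gene_id, j.three_gene_id, paralogs)
            ],
            "iso": lambda js: same_isoform_filter(js, ann),
            "exon": lambda js: exon_filter(js, exon_seqs),
            "sim": lambda js: similarity_filter(js, ann, genome),
        }
        results = set()
        for order in itertools.permutations(stages):
            js = junctions
            for name in order:
                js = stages[name](js)
            results.add(frozenset(j.junction_id for j in js))
        assert len(results) == 1

    def test_filters_do_not_mutate_records(self, decoy_world):
        genome = load_genome(decoy_world.fasta)
        ann = load_annotation(decoy_world.gtf)
        paralogs = load_paralogs(decoy_world.paralogs_tsv)
        combos = [
            c
            for f, t in enumerate_candidate_pairs(ann)
            for c in enumerate_exon_combinations(f, t)
        ]
        junctions, _ = run_prefilter_cascade(combos, ann, genome, paralogs)
        for j in junctions:
            assert len(j.sequence) == 2 * j.flank
            assert j.distance == abs(j.acceptor_bp.position - j.donor_bp.position)
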