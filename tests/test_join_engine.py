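import random

import pytest

from cobra_rejoin.contig_index import (
    Contig,
    ContigEnd,
    ContigSet,
    JoinParams,
    Side,
    build_overlap_index,
    reverse_complement,
)
from cobra_rejoin.evidence import LinkageEvidence
from cobra_rejoin.join_engine import (
    Category,
    OrientedContig,
    detect_self_circular,
    extend_query,
    longest_terminal_repeat,
    merge_walk_sequence,
    next_join,
    resolve_cross_query_conflicts,
    run_cobra,
    summarize,
)
from conftest import full_linkage, make_chain, random_seq

L = 99
PARAMS = JoinParams(assembler="metaspades", maxk=99, mink=21)


def cov_of(contigs):
    return {c.id: c.coverage for c in contigs}


class TestTerminalRepeat:
    def test_exact_repeat_found(self, rng):
        core = random_seq(rng, 2000)
        seq = core + core[:150]
        assert longest_terminal_repeat(seq, 21) == 150

    def test_below_min_reports_zero(self, rng):
        core = random_seq(rng, 2000)
        seq = core + core[:15]
        assert longest_terminal_repeat(seq, 21) == 0

    def test_one_mismatch_disqualifies(self, rng):
        core = random_seq(rng, 2000)
        rep = core[:150]
        broken = rep[:75] + ("A" if rep[75] != "A" else "C") + rep[76:]
        assert longest_terminal_repeat(core + broken, 21) < 75


class TestDetectSelfCircular:
    def test_case1_full_end_overlap(self, rng):
        s = random_seq(rng, L)
        seq = s + random_seq(rng, 1500) + s
        contigs = ContigSet([Contig("q", seq, 20.0)])
        idx = build_overlap_index(contigs, L)
        res = detect_self_circular(contigs["q"], idx, PARAMS)
        assert res is not None and res.category is Category.SELF_CIRCULAR
        assert len(res.joined_seq) == len(seq) - L
        assert res.trim_note == L

    def test_case2_short_terminal_repeat(self, rng):
        core = random_seq(rng, 2000)
        seq = core + core[:30]  # 30 bp DTR, below L
        contigs = ContigSet([Contig("q", seq, 20.0)])
        idx = build_overlap_index(contigs, L)
        res = detect_self_circular(contigs["q"], idx, PARAMS)
        assert res is not None
        assert len(res.joined_seq) == len(seq) - 30

    def test_long_dtr_beyond_end_length(self, rng):
        # a 150 bp DTR does not reproduce the assembler's exact-L end pair
        # (the end L-mers differ), but the terminal-repeat scan still
        # certifies circularity with the full 150 bp trimmed
        core = random_seq(rng, 2000)
        seq = core + core[:150]
        contigs = ContigSet([Contig("q", seq, 20.0)])
        idx = build_overlap_index(contigs, L)
        left, right = ContigEnd("q", Side.LEFT), ContigEnd("q", Side.RIGHT)
        assert idx.partners_of(left) == [] and idx.partners_of(right) == []
        res = detect_self_circular(contigs["q"], idx, PARAMS)
        assert res is not None
        assert len(res.joined_seq) == 2000

    def test_plain_linear_contig_not_circular(self, rng):
        contigs = ContigSet([Contig("q", random_seq(rng, 2000), 20.0)])
        idx = build_overlap_index(contigs, L)
        assert detect_self_circular(contigs["q"], idx, PARAMS) is None


class TestNextJoin:
    def chain(self, rng, cov_b=21.0):
        s = random_seq(rng, L)
        contigs = ContigSet([
            Contig("q", random_seq(rng, 500) + s, 20.0),
            Contig("b", s + random_seq(rng, 500), cov_b),
        ])
        return contigs, build_overlap_index(contigs, L)

    def test_one_path_accept(self, rng):
        contigs, idx = self.chain(rng)
        link = full_linkage(contigs, [("q", "b")], count=3)
        d = next_join(ContigEnd("q", Side.RIGHT), idx, contigs, cov_of(contigs),
                      link, PARAMS, query_cov=20.0, extend_right=True)
        assert d.action == "accept"
        assert d.candidate == OrientedContig("b", forward=True)

    def test_one_path_coverage_fail(self, rng):
        contigs, idx = self.chain(rng, cov_b=90.0)
        link = full_linkage(contigs, [("q", "b")], count=3)
        d = next_join(ContigEnd("q", Side.RIGHT), idx, contigs, cov_of(contigs),
                      link, PARAMS, query_cov=20.0, extend_right=True)
        assert d.action == "fail" and "coverage" in d.reason

    def test_one_path_no_spanning_pairs_fail(self, rng):
        contigs, idx = self.chain(rng)
        d = next_join(ContigEnd("q", Side.RIGHT), idx, contigs, cov_of(contigs),
                      LinkageEvidence(), PARAMS, query_cov=20.0, extend_right=True)
        assert d.action == "fail" and "spanning" in d.reason

    def test_two_paths_strain_variant_resolved_by_coverage(self, rng):
        # C is a low-abundance strain variant at 5x; query and B are 20x
        s = random_seq(rng, L)
        contigs = ContigSet([
            Contig("q", random_seq(rng, 500) + s, 20.0),
            Contig("b", s + random_seq(rng, 500), 20.0),
            Contig("c", s + random_seq(rng, 500), 5.0),
        ])
        idx = build_overlap_index(contigs, L)
        link = full_linkage(contigs, [("q", "b"), ("q", "c")], count=3)
        d = next_join(ContigEnd("q", Side.RIGHT), idx, contigs, cov_of(contigs),
                      link, PARAMS, query_cov=20.0, extend_right=True)
        assert d.action == "accept"
        assert d.candidate.contig_id == "b"

    def test_two_paths_both_pass_is_ambiguous(self, rng):
        s = random_seq(rng, L)
        contigs = ContigSet([
            Contig("q", random_seq(rng, 500) + s, 20.0),
            Contig("b", s + random_seq(rng, 500), 20.0),
            Contig("c", s + random_seq(rng, 500), 21.0),
        ])
        idx = build_overlap_index(contigs, L)
        link = full_linkage(contigs, [("q", "b"), ("q", "c")], count=3)
        d = next_join(ContigEnd("q", Side.RIGHT), idx, contigs, cov_of(contigs),
                      link, PARAMS, query_cov=20.0, extend_right=True)
        assert d.action == "fail" and "ambiguous" in d.reason

    def test_missing_coverage_entry_is_error(self, rng):
        contigs, idx = self.chain(rng)
        cov = {"q": 20.0}
        with pytest.raises(KeyError):
            next_join(ContigEnd("q", Side.RIGHT), idx, contigs, cov,
                      full_linkage(contigs, [("q", "b")]), PARAMS,
                      query_cov=20.0, extend_right=True)


class TestExtendQuery:
    def test_chain_extends_partial(self, rng):
        genome, contigs, ids = make_chain(rng, 3, L)
        idx = build_overlap_index(contigs, L)
        link = full_linkage(contigs)
        res = extend_query(contigs[ids[0]], idx, contigs, cov_of(contigs), link, PARAMS)
        assert res.category is Category.EXTENDED_PARTIAL
        assert len(res.walk) == 3
        assert res.joined_seq == genome

    def test_middle_query_extends_both_directions(self, rng):
        genome, contigs, ids = make_chain(rng, 3, L)
        idx = build_overlap_index(contigs, L)
        link = full_linkage(contigs)
        res = extend_query(contigs[ids[1]], idx, contigs, cov_of(contigs), link, PARAMS)
        assert res.joined_seq == genome
        assert len(res.left_added) == 1 and len(res.right_added) == 1

    def test_ring_extends_circular(self, rng):
        circle = random_seq(rng, 900)
        ring = circle + circle
        pts = [0, 300, 600]
        contigs = ContigSet([
            Contig(f"r{j}", ring[p : pts[j + 1] + L if j < 2 else 900 + L], 20.0)
            for j, p in enumerate(pts)
        ])
        idx = build_overlap_index(contigs, L)
        link = full_linkage(contigs, [("r0", "r1"), ("r1", "r2"), ("r2", "r0")])
        res = extend_query(contigs["r0"], idx, contigs, cov_of(contigs), link, PARAMS)
        assert res.category is Category.EXTENDED_CIRCULAR
        assert len(res.joined_seq) == 900
        assert res.joined_seq in circle + circle  # rotation of the genome

    def test_orphan_end(self, rng):
        contigs = ContigSet([
            Contig("q", random_seq(rng, 500), 20.0),
            Contig("other", random_seq(rng, 500), 20.0),
        ])
        idx = build_overlap_index(contigs, L)
        res = extend_query(contigs["q"], idx, contigs, cov_of(contigs),
                           LinkageEvidence(), PARAMS)
        assert res.category is Category.ORPHAN_END

    def test_partner_without_valid_join_is_extended_failed(self, rng):
        genome, contigs, ids = make_chain(rng, 2, L)
        idx = build_overlap_index(contigs, L)
        res = extend_query(contigs[ids[0]], idx, contigs, cov_of(contigs),
                           LinkageEvidence(), PARAMS)  # no spanning reads at all
        assert res.category is Category.EXTENDED_FAILED
        assert res.walk == [] and res.joined_seq is None


class TestMergeWalk:
    def test_linear_length_law(self, rng):
        genome, contigs, ids = make_chain(rng, 2, L, core_len=201)
        walk = [OrientedContig(i) for i in ids]
        merged = merge_walk_sequence(walk, contigs, L, circular=False)
        total = sum(contigs[i].length for i in ids)
        assert len(merged) == total - L
        assert merged == genome

    def test_single_contig_identity(self, rng):
        contigs = ContigSet([Contig("a", random_seq(rng, 300))])
        assert merge_walk_sequence([OrientedContig("a")], contigs, L, False) == contigs["a"].seq

    def test_three_ring_circular_length(self, rng):
        circle = random_seq(rng, 3 * 201)
        ring = circle + circle
        contigs = ContigSet([
            Contig(f"r{j}", ring[j * 201 : (j + 1) * 201 + L]) for j in range(3)
        ])
        walk = [OrientedContig(f"r{j}") for j in range(3)]
        merged = merge_walk_sequence(walk, contigs, L, circular=True)
        assert len(merged) == sum(c.length for c in contigs) - 3 * L == 603

    def test_reverse_orientation_member(self, rng):
        genome, contigs, ids = make_chain(rng, 2, L)
        flipped = ContigSet([
            contigs[ids[0]],
            Contig("b_rc", reverse_complement(contigs[ids[1]].seq)),
        ])
        walk = [OrientedContig(ids[0]), OrientedContig("b_rc", forward=False)]
        assert merge_walk_sequence(walk, flipped, L, False) == genome

    def test_overlap_mismatch_is_hard_error(self, rng):
        contigs = ContigSet([
            Contig("a", random_seq(rng, 300)),
            Contig("b", random_seq(rng, 300)),
        ])
        with pytest.raises(RuntimeError):
            merge_walk_sequence([OrientedContig("a"), OrientedContig("b")], contigs, L, False)


class TestConflictResolution:
    def test_shared_contig_fails_both_queries(self, rng):
        # two distinct walks both claiming contig "shared"
        genome, contigs, ids = make_chain(rng, 3, L)
        idx = build_overlap_index(contigs, L)
        link = full_linkage(contigs)
        cov = cov_of(contigs)
        r0 = extend_query(contigs[ids[0]], idx, contigs, cov, link, PARAMS)
        # forge a second result with an overlapping but different member set
        from dataclasses import replace
        r1 = replace(r0, query_id="fake", walk=r0.walk[1:])
        out = resolve_cross_query_conflicts([r0, r1], contigs)
        assert all(r.category is Category.EXTENDED_FAILED for r in out)

    def test_identical_walks_not_conflicting(self, rng):
        genome, contigs, ids = make_chain(rng, 3, L)
        idx = build_overlap_index(contigs, L)
        link = full_linkage(contigs)
        cov = cov_of(contigs)
        results = [
            extend_query(contigs[i], idx, contigs, cov, link, PARAMS) for i in ids
        ]
        out = resolve_cross_query_conflicts(results, contigs)
        assert all(r.category is Category.EXTENDED_PARTIAL for r in out)

    def test_both_end_convergence_on_near_duplicates(self, rng):
        # left walk adds X, right walk adds X' which is a 99%-identical variant
        from dataclasses import replace
        x = random_seq(rng, 2000)
        xp = list(x)
        for p in random.Random(1).sample(range(2000), 20):
            xp[p] = "A" if xp[p] != "A" else "C"
        contigs = ContigSet([
            Contig("q", random_seq(rng, 500), 20.0),
            Contig("x", x, 20.0),
            Contig("xp", "".join(xp), 20.0),
        ])
        res = resolve_cross_query_conflicts(
            [
                replace(
                    __import__("cobra_rejoin.join_engine", fromlist=["ExtensionResult"]).ExtensionResult(
                        "q", Category.EXTENDED_PARTIAL,
                        walk=[OrientedContig("x"), OrientedContig("q"), OrientedContig("xp")],
                        joined_seq="ACGT",
                    ),
                    left_added=[OrientedContig("x")],
                    right_added=[OrientedContig("xp")],
                )
            ],
            contigs,
        )
        assert res[0].category is Category.EXTENDED_FAILED

    def test_disjoint_walks_unchanged(self, rng):
        g1, c1, ids1 = make_chain(rng, 2, L)
        g2, c2, ids2 = make_chain(random.Random(99), 2, L)
        contigs = ContigSet(list(c1) + [Contig(f"h_{c.id}", c.seq, c.coverage) for c in c2])
        idx = build_overlap_index(contigs, L)
        link = full_linkage(contigs, [(ids1[0], ids1[1]), (f"h_{ids2[0]}", f"h_{ids2[1]}")])
        cov = cov_of(contigs)
        results = [
            extend_query(contigs[ids1[0]], idx, contigs, cov, link, PARAMS),
            extend_query(contigs[f"h_{ids2[0]}"], idx, contigs, cov, link, PARAMS),
        ]
        out = resolve_cross_query_conflicts(results, contigs)
        assert [r.category for r in out] == [Category.EXTENDED_PARTIAL] * 2


class TestRunCobra:
    def build(self, rng, n=3):
        genome, contigs, ids = make_chain(rng, n, L)
        return genome, contigs, ids, cov_of(contigs), full_linkage(contigs)

    def test_every_query_in_exactly_one_category(self, rng):
        genome, contigs, ids, cov, link = self.build(rng)
        results = run_cobra(contigs, ids, cov, link, PARAMS)
        assert sorted(r.query_id for r in results) == sorted(ids)
        assert sum(summarize(results).values()) == len(ids)

    def test_deterministic_across_input_shuffle(self, rng):
        genome, contigs, ids, cov, link = self.build(rng)
        r1 = run_cobra(contigs, ids, cov, link, PARAMS)
        r2 = run_cobra(contigs, list(reversed(ids)), cov, link, PARAMS)
        key = lambda rs: sorted((r.query_id, r.category.value, r.joined_seq) for r in rs)
        assert key(r1) == key(r2)

    def test_unknown_query_rejected(self, rng):
        genome, contigs, ids, cov, link = self.build(rng)
        with pytest.raises(KeyError):
            run_cobra(contigs, ["nope"], cov, link, PARAMS)

    def test_empty_query_set(self, rng):
        genome, contigs, ids, cov, link = self.build(rng)
        results = run_cobra(contigs, [], cov, link, PARAMS)
        assert results == []

    def test_extended_longer_than_query(self, rng):
        genome, contigs, ids, cov, link = self.build(rng)
        for r in run_cobra(contigs, ids, cov, link, PARAMS):
            if r.category in (Category.EXTENDED_PARTIAL, Category.EXTENDED_CIRCULAR):
                assert len(r.joined_seq) > contigs[r.query_id].length

    def test_idempotence_no_further_joins(self, rng):
        genome, contigs, ids, cov, link = self.build(rng)
        results = run_cobra(contigs, ids, cov, link, PARAMS)
        joined = next(r.joined_seq for r in results if r.category is Category.EXTENDED_PARTIAL)
        # re-run with the joined sequence added as a new query
        contigs2 = ContigSet(list(contigs) + [Contig("joined", joined, 20.0)])
        results2 = run_cobra(contigs2, ["joined"], cov | {"joined": 20.0}, link, PARAMS)
        (r,) = results2
        assert r.category in (Category.ORPHAN_END, Category.EXTENDED_FAILED)
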