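"""Query extension: classify queries and construct joined sequences.

Each query contig is first tested for self-circularity (its own terminal
repeat closes the genome), then extended outwards from both ends one contig
at a time. A candidate join is accepted only when the end pairing is
unambiguous (one or two candidate paths), the candidate's depth is within the
coverage-ratio window of the query's, and read pairs span the two contigs.
Queries are finally assigned to one of five categories:

* ``self_circular`` — a single contig circularized by its terminal repeat;
* ``extended_circular`` — the extension looped back to the query's other end;
* ``extended_partial`` — extended but still linear;
* ``extended_failed`` — at least one end had overlap partners, but no join
  survived validation (or a cross-query path conflict was detected);
* ``orphan_end`` — neither end shares its sequence with any other end.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

from cobra_rejoin.contig_index import (
    Contig,
    ContigEnd,
    ContigSet,
    EndClass,
    JoinParams,
    OverlapIndex,
    Side,
    build_overlap_index,
    reverse_complement,
)
from cobra_rejoin.evidence import (
    CoverageMap,
    LinkageEvidence,
    coverage_compatible,
)

logger = logging.getLogger(__name__)


class Category(str, enum.Enum):
    SELF_CIRCULAR = "self_circular"
    EXTENDED_CIRCULAR = "extended_circular"
    EXTENDED_PARTIAL = "extended_partial"
    EXTENDED_FAILED = "extended_failed"
    ORPHAN_END = "orphan_end"


@dataclass(frozen=True)
class OrientedContig:
    """A contig used as-is (forward) or reverse-complemented in a walk."""

    contig_id: str
    forward: bool = True

    def __str__(self) -> str:
        return f"{self.contig_id}{'+' if self.forward else '-'}"


@dataclass
class ExtensionResult:
    query_id: str
    category: Category
    walk: list[OrientedContig] = field(default_factory=list)
    joined_seq: str | None = None
    trim_note: int = 0  # terminal bases trimmed for circular outputs
    left_added: list[OrientedContig] = field(default_factory=list)
    right_added: list[OrientedContig] = field(default_factory=list)
    fail_reason: str | None = None


@dataclass(frozen=True)
class JoinDecision:
    """Outcome of evaluating one end for its next join."""

    action: str  # "accept" | "stop" | "fail"
    candidate: OrientedContig | None = None
    via: ContigEnd | None = None
    reason: str | None = None


def longest_terminal_repeat(seq: str, min_len: int) -> int:
    """Length of the longest exact direct terminal repeat, or 0 if < min_len.

    A terminal repeat of length d means ``seq[:d] == seq[-d:]`` — a border of
    the string, found with the KMP failure function in linear time. Repeats
    longer than half the sequence are ignored (the "repeat" would cover the
    whole contig).
    """
    n = len(seq)
    fail = [0] * (n + 1)
    k = 0
    for i in range(1, n):
        while k and seq[i] != seq[k]:
            k = fail[k]
        if seq[i] == seq[k]:
            k += 1
        fail[i + 1] = k
    border = fail[n]
    while border > n // 2:
        border = fail[border]
    return border if border >= min_len else 0


def oriented_seq(contig: Contig, forward: bool) -> str:
    return contig.seq if forward else reverse_complement(contig.seq)


def detect_self_circular(
    query: Contig, index: OverlapIndex, params: JoinParams
) -> ExtensionResult | None:
    """Detect a query whose own terminal repeat closes a circular genome.

    Case 1: the query's left and right ends are each other's exclusive
    partners at the full end length L — the assembler's own overlap signature
    for a circular sequence. Case 2: neither end has any partner, but the
    contig carries an exact direct terminal repeat of length >= minK (for
    example a DTR genome assembled in one piece, whose repeat length differs
    from L and therefore escapes the end index). One repeat copy is trimmed
    from the reported circular sequence.
    """
    L = index.L
    if query.length < L:
        return None
    left = ContigEnd(query.id, Side.LEFT)
    right = ContigEnd(query.id, Side.RIGHT)
    p_left = index.partners_of(left)
    p_right = index.partners_of(right)

    if p_left == [right] and p_right == [left]:
        d = L
    elif not p_left and not p_right:
        d = longest_terminal_repeat(query.seq, params.mink)
        if not d:
            return None
    else:
        return None
    return ExtensionResult(
        query_id=query.id,
        category=Category.SELF_CIRCULAR,
        walk=[OrientedContig(query.id)],
        joined_seq=query.seq[:-d],
        trim_note=d,
    )


def next_join(
    current_end: ContigEnd,
    index: OverlapIndex,
    contigs: ContigSet,
    coverage: CoverageMap,
    linkage: LinkageEvidence,
    params: JoinParams,
    query_cov: float,
    extend_right: bool,
) -> JoinDecision:
    """Decide whether and how the walk continues past ``current_end``.

    no_match and multi_path ends stop the search. A one_path_end accepts its
    unique partner iff the coverage ratio and spanning-pair requirements hold,
    otherwise the join fails. A two_paths_end accepts the single passing
    candidate among its two partners; zero or two passing candidates fail the
    join (the path would be ambiguous).
    """
    cls = index.classify(current_end)
    if cls is EndClass.NO_MATCH:
        return JoinDecision("stop", reason="no_match")
    if cls is EndClass.MULTI_PATH:
        return JoinDecision("stop", reason="multi_path")

    def evaluate(partner: ContigEnd) -> tuple[bool, str]:
        if partner.contig_id not in coverage:
            raise KeyError(
                f"contig {partner.contig_id!r} has no coverage entry but is a join candidate"
            )
        cand_cov = coverage[partner.contig_id]
        if not coverage_compatible(query_cov, cand_cov, params.cov_ratio_window):
            return False, f"coverage ratio {cand_cov:.3g}/{query_cov:.3g} outside window"
        spans = linkage.count(current_end.contig_id, partner.contig_id)
        if spans < params.min_spanning_pairs:
            return False, f"only {spans} spanning pairs (< {params.min_spanning_pairs})"
        return True, "ok"

    def orient(partner: ContigEnd) -> OrientedContig:
        # Walking rightward, a left-side partner continues forward and a
        # right-side partner is entered through its rc; mirrored leftward.
        if extend_right:
            return OrientedContig(partner.contig_id, partner.side is Side.LEFT)
        return OrientedContig(partner.contig_id, partner.side is Side.RIGHT)

    partners = index.partners_of(current_end)
    if cls is EndClass.ONE_PATH:
        (partner,) = partners
        ok, why = evaluate(partner)
        if ok:
            return JoinDecision("accept", candidate=orient(partner), via=partner)
        return JoinDecision("fail", reason=why)

    # two_paths_end: exactly one of the two candidates may pass.
    passing = []
    reasons = []
    for partner in partners:
        ok, why = evaluate(partner)
        if ok:
            passing.append(partner)
        else:
            reasons.append(f"{partner}: {why}")
    if len(passing) == 1:
        partner = passing[0]
        return JoinDecision("accept", candidate=orient(partner), via=partner)
    if not passing:
        return JoinDecision("fail", reason="; ".join(reasons))
    return JoinDecision("fail", reason="both candidate paths pass; join ambiguous")


def _outgoing_end(tip: OrientedContig, extend_right: bool) -> ContigEnd:
    if extend_right:
        side = Side.RIGHT if tip.forward else Side.LEFT
    else:
        side = Side.LEFT if tip.forward else Side.RIGHT
    return ContigEnd(tip.contig_id, side)


def extend_query(
    query: Contig,
    index: OverlapIndex,
    contigs: ContigSet,
    coverage: CoverageMap,
    linkage: LinkageEvidence,
    params: JoinParams,
) -> ExtensionResult:
    """Classify one query and build its walk of joined contigs."""
    self_circ = detect_self_circular(query, index, params)
    if self_circ is not None:
        return self_circ

    left = ContigEnd(query.id, Side.LEFT)
    right = ContigEnd(query.id, Side.RIGHT)
    has_partner = bool(index.partners_of(left)) or bool(index.partners_of(right))
    if not has_partner:
        return ExtensionResult(query.id, Category.ORPHAN_END)

    query_cov = coverage.get(query.id)
    if query_cov is None:
        raise KeyError(f"query {query.id!r} has no coverage entry")

    walk: list[OrientedContig] = [OrientedContig(query.id)]
    used = {query.id}
    circular = False
    fail_reasons: list[str] = []
    left_added: list[OrientedContig] = []
    right_added: list[OrientedContig] = []

    for extend_right, added in ((True, right_added), (False, left_added)):
        while True:
            tip = walk[-1] if extend_right else walk[0]
            decision = next_join(
                _outgoing_end(tip, extend_right),
                index, contigs, coverage, linkage, params, query_cov, extend_right,
            )
            if decision.action == "stop":
                break
            if decision.action == "fail":
                fail_reasons.append(decision.reason or "join invalid")
                logger.debug("query %s: join rejected (%s)", query.id, decision.reason)
                break
            cand = decision.candidate
            assert cand is not None
            if cand.contig_id == query.id:
                # Looped back onto the query itself: closes the circle only
                # when arriving forward onto the query's far end.
                if cand.forward and len(walk) > 1:
                    circular = True
                break
            if cand.contig_id in used:
                break  # repeat revisit; stop this direction
            logger.debug("query %s: accepted %s via %s", query.id, cand, decision.via)
            if extend_right:
                walk.append(cand)
            else:
                walk.insert(0, cand)
            added.append(cand)
            used.add(cand.contig_id)
        if circular:
            break

    if circular:
        # Rotate the walk so the query leads, as recorded categories expect.
        qi = next(i for i, oc in enumerate(walk) if oc.contig_id == query.id)
        walk = walk[qi:] + walk[:qi]
        seq = merge_walk_sequence(walk, contigs, index.L, circular=True)
        return ExtensionResult(
            query.id, Category.EXTENDED_CIRCULAR, walk, seq,
            trim_note=index.L, left_added=left_added, right_added=right_added,
        )
    if len(walk) > 1:
        seq = merge_walk_sequence(walk, contigs, index.L, circular=False)
        return ExtensionResult(
            query.id, Category.EXTENDED_PARTIAL, walk, seq,
            left_added=left_added, right_added=right_added,
        )
    return ExtensionResult(
        query.id, Category.EXTENDED_FAILED,
        fail_reason="; ".join(fail_reasons) or "no valid join at any end",
    )


def merge_walk_sequence(
    walk: list[OrientedContig], contigs: ContigSet, L: int, circular: bool
) -> str:
    """Concatenate a walk, dropping one copy of each internal L-overlap.

    Linear length is the member-length sum minus (n-1)*L; a circular walk
    additionally trims the final L-overlap that closes the loop. Junction
    sequences are re-verified; a mismatch is an internal-consistency error.
    """
    if not walk:
        raise ValueError("empty walk")
    pieces = [oriented_seq(contigs[oc.contig_id], oc.forward) for oc in walk]
    merged = [pieces[0]]
    for prev, cur, oc in zip(pieces, pieces[1:], walk[1:]):
        if prev[-L:] != cur[:L]:
            raise RuntimeError(f"walk overlap mismatch entering {oc}")
        merged.append(cur[L:])
    seq = "".join(merged)
    if circular:
        if seq[-L:] != pieces[0][:L]:
            raise RuntimeError("circular walk does not close: terminal overlap mismatch")
        seq = seq[:-L]
    return seq


def _canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        out.add(min(kmer, reverse_complement(kmer)))
    return out


def _kmer_containment(a: str, b: str, k: int) -> float:
    ka, kb = _canonical_kmers(a, k), _canonical_kmers(b, k)
    if not ka or not kb:
        return 0.0
    return len(ka & kb) / min(len(ka), len(kb))


def resolve_cross_query_conflicts(
    results: list[ExtensionResult],
    contigs: ContigSet,
    *,
    kmer_size: int = 16,
    min_identity: float = 0.95,
) -> list[ExtensionResult]:
    """Demote joins whose paths are not globally unique.

    (a) If a contig is claimed by the walks of two or more distinct final
    sequences (walks with different member sets), every query involved is
    reassigned extended_failed — the path was only seemingly unique.
    (b) If the two directional extensions of one query pulled in distinct
    contigs that are near-duplicates of each other, both ends converged into
    closely related sequences — typically strain variants — and the query is
    reassigned extended_failed. Relatedness is estimated Mash-style from
    canonical k-mer containment, identity ~= containment**(1/k); the default
    threshold of 0.95 flags species-level relatives while chance repeats
    between unrelated contigs stay far below it.
    """
    out = list(results)
    extended = [
        i for i, r in enumerate(out)
        if r.category in (Category.EXTENDED_CIRCULAR, Category.EXTENDED_PARTIAL)
    ]

    # (a) shared-contig conflicts between walks with different member sets
    claims: dict[str, list[int]] = {}
    for i in extended:
        for oc in out[i].walk:
            claims.setdefault(oc.contig_id, []).append(i)
    conflicted: set[int] = set()
    for cid, holders in claims.items():
        if len(holders) < 2:
            continue
        member_sets = {frozenset(oc.contig_id for oc in out[h].walk) for h in holders}
        if len(member_sets) > 1:
            conflicted.update(holders)
    for i in conflicted:
        r = out[i]
        logger.info("query %s: path conflict with another query; extended_failed", r.query_id)
        out[i] = replace(
            r, category=Category.EXTENDED_FAILED, walk=[], joined_seq=None,
            trim_note=0, fail_reason="path claimed by multiple distinct joins",
        )

    # (b) both-end convergence onto closely related sequences
    for i in extended:
        if i in conflicted:
            continue
        r = out[i]
        hit = None
        for lc in r.left_added:
            for rcand in r.right_added:
                if lc.contig_id == rcand.contig_id:
                    continue
                c = _kmer_containment(
                    contigs[lc.contig_id].seq, contigs[rcand.contig_id].seq, kmer_size
                )
                identity = c ** (1.0 / kmer_size) if c > 0 else 0.0
                if identity >= min_identity:
                    hit = (lc.contig_id, rcand.contig_id, identity)
                    break
            if hit:
                break
        if hit:
            logger.info(
                "query %s: extensions converge on near-duplicates %s/%s (containment %.2f)",
                r.query_id, *hit,
            )
            out[i] = replace(
                r, category=Category.EXTENDED_FAILED, walk=[], joined_seq=None,
                trim_note=0,
                fail_reason=f"both-end extensions are near-duplicates ({hit[0]}, {hit[1]})",
            )
    return out


def run_cobra(
    contigs: ContigSet,
    query_ids: list[str],
    coverage: CoverageMap,
    linkage: LinkageEvidence,
    params: JoinParams,
) -> list[ExtensionResult]:
    """Run the full joining pipeline over a set of query contigs.

    Queries are processed in descending length (ties by id) for
    deterministic output. Every query receives exactly one category.
    """
    missing = [q for q in query_ids if q not in contigs]
    if missing:
        raise KeyError(f"query ids absent from assembly: {missing[:5]}")
    for q in query_ids:
        if q not in coverage:
            raise KeyError(f"query {q!r} has no coverage entry")

    index = build_overlap_index(contigs, params.end_len)
    ordered = sorted(set(query_ids), key=lambda q: (-contigs[q].length, q))
    results = [
        extend_query(contigs[q], index, contigs, coverage, linkage, params)
        for q in ordered
    ]
    return resolve_cross_query_conflicts(results, contigs)


def summarize(results: list[ExtensionResult]) -> dict[str, int]:
    """Per-category query counts."""
    counts = {c.value: 0 for c in Category}
    for r in results:
        counts[r.category.value] += 1
    return counts
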