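"""Reference-based evaluation of joins and bins: purity labels, contamination
rate, pairwise confusion metrics and RPKM abundance.

A group (one join's member contigs, or one bin) is compared against the
reference genomes its contigs best match. All members matching one reference
makes the group *good*; members split across references that are closely
related (pairwise ANI at or above a threshold, 70% by default) make it
*problematic*; any reference pair below the threshold makes it
*contaminated*. For non-good groups a length-weighted contamination rate is
computed, normalized so that an even split of length across all matched
references scores 100%.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass


class GroupLabel(str, enum.Enum):
    GOOD = "good"
    PROBLEMATIC = "problematic"
    CONTAMINATED = "contaminated"


@dataclass(frozen=True)
class MemberMatch:
    """One group member: contig id, its length, and its best-match reference."""

    contig_id: str
    length: int
    best_ref: str


@dataclass(frozen=True)
class GroupEvaluation:
    group_id: str
    member_contigs: frozenset[str]
    matched_refs: frozenset[str]
    label: GroupLabel
    total_len: int
    max_len: int
    num_polished: int
    contamination: float  # 0 for good groups


def contamination_rate(total_len: int, max_len: int, num_polished: int) -> float:
    """Normalized length-weighted contamination of a multi-reference group.

    rate = ((Total_len - Max_len) / Total_len) / ((Num_polished - 1) / Num_polished)

    where Max_len is the summed length of contigs matching the dominant
    reference and Num_polished the number of matched references. The
    normalization makes an even length split across all matched references
    score exactly 1.0 (the theoretical maximum).
    """
    if num_polished < 2:
        raise ValueError("contamination rate is undefined for single-reference groups")
    if not 0 < max_len <= total_len:
        raise ValueError("need 0 < max_len <= total_len")
    return ((total_len - max_len) / total_len) / ((num_polished - 1) / num_polished)


def _ani_lookup(ani: dict, ref_a: str, ref_b: str) -> float:
    for key in ((ref_a, ref_b), (ref_b, ref_a), frozenset((ref_a, ref_b))):
        if key in ani:
            return ani[key]
    raise KeyError(f"no ANI entry for reference pair ({ref_a}, {ref_b})")


def classify_group(
    group_id: str,
    members: list[MemberMatch],
    ani: dict | None = None,
    ani_threshold: float = 70.0,
) -> GroupEvaluation:
    """Label a group good/problematic/contaminated against its matched references.

    ``ani`` maps reference pairs (tuples in either order, or frozensets) to
    percent identity; it is only consulted for multi-reference groups. The
    result is invariant to member order.
    """
    if not members:
        raise ValueError(f"group {group_id!r} has no members")
    refs = sorted({m.best_ref for m in members})
    total_len = sum(m.length for m in members)
    len_by_ref = {r: sum(m.length for m in members if m.best_ref == r) for r in refs}
    max_len = max(len_by_ref.values())

    if len(refs) == 1:
        label = GroupLabel.GOOD
        contamination = 0.0
    else:
        if ani is None:
            raise ValueError(f"group {group_id!r} matches multiple references; ANI table required")
        if all(
            _ani_lookup(ani, a, b) >= ani_threshold
            for a, b in itertools.combinations(refs, 2)
        ):
            label = GroupLabel.PROBLEMATIC
        else:
            label = GroupLabel.CONTAMINATED
        contamination = contamination_rate(total_len, max_len, len(refs))

    return GroupEvaluation(
        group_id=group_id,
        member_contigs=frozenset(m.contig_id for m in members),
        matched_refs=frozenset(refs),
        label=label,
        total_len=total_len,
        max_len=max_len,
        num_polished=len(refs),
        contamination=contamination,
    )


def confusion_metrics(
    truth: dict[str, str], predicted: dict[str, str]
) -> dict[str, float]:
    """Pairwise clustering metrics over unordered contig co-membership pairs.

    ``truth`` and ``predicted`` map contig id to a group label. The
    evaluation universe is every unordered pair of contigs appearing in
    either mapping; a contig absent from a mapping is treated as a singleton
    there. Returns precision, recall, F1, specificity and accuracy; an
    undefined ratio (empty denominator) is reported as 0.
    """
    universe = sorted(set(truth) | set(predicted))
    if len(universe) < 2:
        raise ValueError("need at least two contigs to form evaluation pairs")

    tp = fp = fn = tn = 0
    for a, b in itertools.combinations(universe, 2):
        same_true = a in truth and b in truth and truth[a] == truth[b]
        same_pred = a in predicted and b in predicted and predicted[a] == predicted[b]
        if same_pred and same_true:
            tp += 1
        elif same_pred:
            fp += 1
        elif same_true:
            fn += 1
        else:
            tn += 1

    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    f1 = ratio(2 * precision * recall, precision + recall) if (precision + recall) else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "specificity": ratio(tn, tn + fp),
        "accuracy": ratio(tp + tn, tp + fp + fn + tn),
    }


def rpkm(n_mapped: int, genome_len: int, n_sample: int) -> float:
    """Reads per kilobase of genome per million mapped sample reads.

    RPKM = N_mapped / (genome_len / 1,000) / (N_sample / 1,000,000).
    """
    if genome_len < 1:
        raise ValueError("genome length must be >= 1 bp")
    if n_sample == 0:
        raise ValueError("no mapped sample reads; RPKM undefined")
    if n_mapped < 0 or n_sample < 0:
        raise ValueError("read counts must be non-negative")
    return n_mapped / (genome_len / 1_000) / (n_sample / 1_000_000)
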