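"""Join-validity evidence: coverage-ratio compatibility and paired-read linkage.

A candidate join is only trusted when the two contigs have similar mean
sequencing depth (fragments of one genome should be sampled at the same rate)
and when at least one properly filtered read pair has one mate on each contig,
physically spanning the putative adjacency.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import pysam

CoverageMap = dict[str, float]


def load_coverage(path: str | Path) -> CoverageMap:
    """Read a two-column TAB-separated table of contig_id -> mean depth.

    No header is required; a repeated id or a non-numeric depth is an error.
    """
    depth: CoverageMap = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two TAB-separated columns")
            cid, raw = fields[0], fields[1]
            if cid in depth:
                raise ValueError(f"{path}:{lineno}: repeated contig id {cid!r}")
            try:
                value = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric depth {raw!r} for {cid!r}"
                ) from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative depth for {cid!r}")
            depth[cid] = value
    return depth


def coverage_compatible(
    cov_query: float, cov_candidate: float, window: tuple[float, float] = (0.5, 2.0)
) -> bool:
    """True iff the candidate/query depth ratio lies inside the window (inclusive).

    A zero-depth query is only compatible with a zero-depth candidate.
    """
    lo, hi = window
    if not (0 < lo <= 1 <= hi):
        raise ValueError(f"coverage window must satisfy 0 < lo <= 1 <= hi, got {window}")
    if cov_query == 0:
        return cov_candidate == 0
    return lo <= cov_candidate / cov_query <= hi


class LinkageEvidence:
    """Counts of filtered read pairs spanning each unordered contig pair."""

    def __init__(self) -> None:
        self._counts: dict[frozenset[str], int] = defaultdict(int)

    def add(self, contig_a: str, contig_b: str, n: int = 1) -> None:
        if contig_a == contig_b:
            raise ValueError("a pair within one contig is not a cross-contig link")
        self._counts[frozenset((contig_a, contig_b))] += n

    def count(self, contig_a: str, contig_b: str) -> int:
        return self._counts.get(frozenset((contig_a, contig_b)), 0)

    def pairs(self) -> dict[frozenset[str], int]:
        return dict(self._counts)

    def __len__(self) -> int:
        return len(self._counts)


def _mismatches(read: "pysam.AlignedSegment") -> int | None:
    try:
        return read.get_tag("NM")
    except KeyError:
        return None


def collect_spanning_pairs(
    alignment_path: str | Path,
    mm_max: int = 2,
    *,
    missing_nm_passes: bool = False,
) -> LinkageEvidence:
    """Count read pairs whose mates map to two different contigs.

    Only primary, mapped alignments contribute. Each mate must have at most
    ``mm_max`` mismatches (NM tag; soft-clipped bases are not mismatches).
    Reads without an NM tag fail the filter unless ``missing_nm_passes``.
    The result is independent of record order in the file.
    """
    path = str(alignment_path)
    mode = "rb" if path.endswith(".bam") else "r"
    evidence = LinkageEvidence()
    # read name -> (contig, passed_filter) for the first mate seen
    pending: dict[str, tuple[str, bool]] = {}

    with pysam.AlignmentFile(path, mode) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired:
                continue
            nm = _mismatches(read)
            ok = missing_nm_passes if nm is None else nm <= mm_max
            contig = read.reference_name
            name = read.query_name
            if name in pending:
                other_contig, other_ok = pending.pop(name)
                if ok and other_ok and contig != other_contig:
                    evidence.add(contig, other_contig)
            else:
                pending[name] = (contig, ok)
    return evidence
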