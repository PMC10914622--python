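"""Contigs, end sequences, and the reverse-complement-aware overlap index.

An assembler that builds its graph with largest k-mer size ``maxK`` leaves an
exact shared sequence of length ``maxK`` (metaSPAdes, MEGAHIT) or ``maxK - 1``
(IDBA_UD) on the two contigs flanking a breakpoint. This module extracts those
fixed-length end sequences from every contig, groups ends that carry the same
sequence in either orientation, and classifies each end by how many distinct
join partners it has.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


class Assembler(str, enum.Enum):
    """Supported de Bruijn graph assemblers."""

    METASPADES = "metaspades"
    MEGAHIT = "megahit"
    IDBA_UD = "idba_ud"


class EndClass(str, enum.Enum):
    """Path-multiplicity classification of a contig end.

    ``ONE_PATH`` — exactly one partner end shares the sequence, so there is a
    single candidate join. ``TWO_PATHS`` — the end (A) shares its sequence with
    exactly two other ends (B, C) which in turn partner exclusively with A;
    typically B and C are strain variants or the two copies of a repeat.
    Anything more promiscuous is ``MULTI_PATH`` and never joined.
    """

    NO_MATCH = "no_match"
    ONE_PATH = "one_path_end"
    TWO_PATHS = "two_paths_end"
    MULTI_PATH = "multi_path_end"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}; N maps to N."""
    invalid = set(seq) - _VALID_BASES
    if invalid:
        raise ValueError(f"invalid DNA characters: {sorted(invalid)}")
    return seq.translate(_COMPLEMENT)[::-1]


def end_length_for(assembler: str | Assembler, maxk: int) -> int:
    """End-sequence length left on contigs by the assembler at its largest k.

    metaSPAdes and MEGAHIT leave ``maxK``-length overlaps; IDBA_UD leaves
    ``maxK - 1``.
    """
    if maxk < 2:
        raise ValueError(f"maxK must be >= 2, got {maxk}")
    asm = Assembler(assembler)
    if asm in (Assembler.METASPADES, Assembler.MEGAHIT):
        return maxk
    return maxk - 1


@dataclass(frozen=True)
class JoinParams:
    """Parameters governing end-overlap detection and join validation.

    ``end_len`` is derived from the assembler and maxK; ``mink`` is the
    smallest terminal-overlap length accepted when calling a contig
    self-circular via a shorter direct terminal repeat. The coverage window
    bounds the candidate/query depth ratio, ``min_spanning_pairs`` is the
    minimum paired-read linkage per join, and ``mm_max`` the per-read
    mismatch allowance when counting those pairs.
    """

    assembler: Assembler
    maxk: int
    mink: int
    cov_ratio_window: tuple[float, float] = (0.5, 2.0)
    min_spanning_pairs: int = 1
    mm_max: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "assembler", Assembler(self.assembler))
        if not self.mink < self.maxk:
            raise ValueError(f"minK ({self.mink}) must be < maxK ({self.maxk})")
        lo, hi = self.cov_ratio_window
        if not (0 < lo <= 1 <= hi):
            raise ValueError(f"coverage window must satisfy lo <= 1 <= hi, got {self.cov_ratio_window}")
        if self.min_spanning_pairs < 1:
            raise ValueError("min_spanning_pairs must be >= 1")
        if self.mm_max < 0:
            raise ValueError("mm_max must be >= 0")

    @property
    def end_len(self) -> int:
        return end_length_for(self.assembler, self.maxk)


@dataclass(frozen=True)
class Contig:
    """An assembled sequence with id, uppercase DNA bases and mean read depth."""

    id: str
    seq: str
    coverage: float = 0.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.seq:
            raise ValueError(f"contig {self.id!r} has an empty sequence")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        if self.coverage < 0:
            raise ValueError(f"contig {self.id!r} has negative coverage")

    @property
    def length(self) -> int:
        return len(self.seq)


class ContigSet:
    """Ordered, id-unique collection of contigs (input FASTA order preserved)."""

    def __init__(self, contigs: Iterator[Contig] | list[Contig] = ()) -> None:
        self._by_id: dict[str, Contig] = {}
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.id in self._by_id:
            raise ValueError(f"duplicate contig id {contig.id!r}")
        self._by_id[contig.id] = contig

    def __getitem__(self, contig_id: str) -> Contig:
        return self._by_id[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._by_id

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def ids(self) -> list[str]:
        return list(self._by_id)

    def with_coverage(self, depth: dict[str, float]) -> "ContigSet":
        """Return a copy whose contigs carry depths from the given map."""
        out = ContigSet()
        for c in self:
            cov = depth.get(c.id, c.coverage)
            out.add(Contig(c.id, c.seq, cov))
        return out


def load_contigs(fasta_path: str | Path) -> ContigSet:
    """Read a FASTA file into a ContigSet; sequences uppercased.

    The record id is the first whitespace-delimited token of the header.
    Duplicate ids, empty sequences and non-ACGTN characters are hard errors.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs = ContigSet()
    for record in SeqIO.parse(str(path), "fasta"):
        contigs.add(Contig(record.id, str(record.seq).upper()))
    return contigs


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True, order=True)
class ContigEnd:
    """An oriented end of a contig: its L-length prefix (left) or suffix (right)."""

    contig_id: str
    side: Side

    def __str__(self) -> str:
        return f"{self.contig_id}:{self.side.value}"


def end_sequence(contig: Contig, side: Side, L: int) -> str:
    return contig.seq[:L] if side is Side.LEFT else contig.seq[-L:]


@dataclass
class OverlapIndex:
    """Map from end L-mer (and its reverse complement) to the ends carrying it.

    ``partners`` maps each end to the sorted set of other ends that share its
    sequence in either orientation; ``classifications`` labels each end by
    partner multiplicity. Ends whose L-mer contains N never match: an
    ambiguous base cannot certify an exact de Bruijn overlap.
    """

    L: int
    table: dict[str, set[ContigEnd]] = field(default_factory=dict)
    partners: dict[ContigEnd, list[ContigEnd]] = field(default_factory=dict)
    classifications: dict[ContigEnd, EndClass] = field(default_factory=dict)
    skipped_short: list[str] = field(default_factory=list)
    _end_seqs: dict[ContigEnd, str] = field(default_factory=dict)

    def end_seq(self, end: ContigEnd) -> str:
        return self._end_seqs[end]

    def classify(self, end: ContigEnd) -> EndClass:
        return self.classifications.get(end, EndClass.NO_MATCH)

    def partners_of(self, end: ContigEnd) -> list[ContigEnd]:
        return self.partners.get(end, [])


def build_overlap_index(contigs: ContigSet, L: int) -> OverlapIndex:
    """Register both end L-mers of every contig under the L-mer and its rc.

    Contigs shorter than L contribute no ends (they are recorded in
    ``skipped_short`` and remain usable as orphan-end queries). Partner sets
    are rc-aware and symmetric; palindromic end sequences are matched once.
    """
    if L <= 0:
        raise ValueError(f"end length must be positive, got {L}")
    index = OverlapIndex(L=L)

    for contig in contigs:
        if contig.length < L:
            index.skipped_short.append(contig.id)
            continue
        for side in (Side.LEFT, Side.RIGHT):
            end = ContigEnd(contig.id, side)
            s = end_sequence(contig, side, L)
            index._end_seqs[end] = s
            if "N" in s:
                continue  # ambiguous ends never certify an exact overlap
            for key in {s, reverse_complement(s)}:
                index.table.setdefault(key, set()).add(end)

    # Partner sets keep only geometrically joinable pairs: a right end can
    # run into a left end carrying the same L-mer (head-to-tail), or into
    # another end of the same side whose L-mer is the reverse complement
    # (head-to-head, candidate used as rc). Sibling matches — two ends that
    # merely read into the same downstream sequence — are not joins.
    for end, s in index._end_seqs.items():
        if "N" in s:
            index.partners[end] = []
            continue
        rc = reverse_complement(s)
        mates: set[ContigEnd] = set()
        for other in index.table.get(s, set()) | index.table.get(rc, set()):
            if other == end:
                continue
            t = index._end_seqs[other]
            if other.side != end.side:
                joinable = t == s
            else:
                joinable = t == rc
            if joinable:
                mates.add(other)
        index.partners[end] = sorted(mates)

    for end in index._end_seqs:
        ps = index.partners.get(end, [])
        if not ps:
            index.classifications[end] = EndClass.NO_MATCH
        elif len(ps) == 1:
            index.classifications[end] = EndClass.ONE_PATH
        elif len(ps) == 2:
            b, c = ps
            # two_paths_end requires B and C to partner exclusively with this end
            if index.partners.get(b, []) == [end] and index.partners.get(c, []) == [end]:
                index.classifications[end] = EndClass.TWO_PATHS
            else:
                index.classifications[end] = EndClass.MULTI_PATH
        else:
            index.classifications[end] = EndClass.MULTI_PATH

    return index
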