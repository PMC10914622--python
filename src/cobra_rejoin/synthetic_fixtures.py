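"""Ground-truthed synthetic viral communities for end-to-end testing.

The generator emulates the ingredients that fragment real metagenome
assemblies and that the joiner must cope with: circular genomes carrying a
100-200 bp direct terminal repeat, subpopulations mutated at 1/3/5% of
bases, contig fragmentation that leaves the assembler's exact L-length end
sequence on both flanks of every breakpoint, per-genome depths of 10-100x,
and 126 bp paired reads. Reads are placed by construction and their
alignments emitted directly from the known coordinates, so NM tags and
coverage are exact and no external aligner is involved.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from cobra_rejoin.contig_index import Contig, ContigSet, reverse_complement

_BASES = "ACGT"


@dataclass(frozen=True)
class Genome:
    id: str
    seq: str  # linear representation; for circular genomes includes the DTR
    is_circular: bool = False
    dtr_len: int = 0
    parent_id: str | None = None
    mutation_rate: float = 0.0

    @property
    def circle_len(self) -> int:
        """Length of the underlying circular genome (seq minus one DTR copy)."""
        return len(self.seq) - self.dtr_len


@dataclass
class SyntheticCommunity:
    genomes: list[Genome]
    depths: dict[str, float]
    seed: int

    def genome(self, gid: str) -> Genome:
        return next(g for g in self.genomes if g.id == gid)


@dataclass(frozen=True)
class TruthRecord:
    """Origin of one contig: genome, 0-based half-open interval, strand.

    For contigs of circular genomes the interval may extend past the circle
    length, meaning it wraps around the origin.
    """

    contig_id: str
    genome_id: str
    start: int
    end: int
    strand: str = "+"


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choices(_BASES, k=n))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    """Substitute `rate` of positions, drawn without replacement."""
    n_mut = round(len(seq) * rate)
    positions = rng.sample(range(len(seq)), n_mut)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in _BASES if b != out[p]])
    return "".join(out)


def simulate_community(
    n_dtr: int = 500,
    n_1p: int = 500,
    n_3p: int = 500,
    n_5p: int = 500,
    n_three: int = 300,
    n_plain: int = 0,
    genome_len_range: tuple[int, int] = (5_000, 50_000),
    depth_range: tuple[float, float] = (10.0, 100.0),
    dtr_len_range: tuple[int, int] = (100, 200),
    seed: int = 0,
) -> SyntheticCommunity:
    """Build a community mixing DTR genomes and mutated subpopulation pairs/trios.

    Five categories: circular genomes given a 100-200 bp direct terminal
    repeat; genome pairs where one copy is mutated at 1%, 3% or 5% of bases
    (the unmutated original is retained); and genome trios of an original
    plus a 3%- and a 5%-mutant. With the default category sizes the total is
    500 + 500*2*3 + 300*3 = 4,400 genomes. Each genome gets a depth drawn
    uniformly from 10-100x. Fully reproducible from the seed.
    """
    rng = random.Random(seed)
    genomes: list[Genome] = []

    for i in range(n_plain):
        # variant-free linear genomes: not part of the headline count, but
        # useful as clean round-trip fixtures
        genomes.append(Genome(f"plain_{i}", _random_seq(rng, rng.randint(*genome_len_range))))

    for i in range(n_dtr):
        gid = f"dtr_{i}"
        glen = rng.randint(*genome_len_range)
        circle = _random_seq(rng, glen)
        dtr = rng.randint(*dtr_len_range)
        genomes.append(Genome(gid, circle + circle[:dtr], is_circular=True, dtr_len=dtr))

    for label, count, rates in (
        ("two_1p", n_1p, (0.01,)),
        ("two_3p", n_3p, (0.03,)),
        ("two_5p", n_5p, (0.05,)),
        ("three", n_three, (0.03, 0.05)),
    ):
        for i in range(count):
            gid = f"{label}_{i}"
            seq = _random_seq(rng, rng.randint(*genome_len_range))
            genomes.append(Genome(gid, seq))
            for rate in rates:
                tag = f"{gid}_m{int(rate * 100)}p"
                genomes.append(
                    Genome(tag, _mutate(rng, seq, rate), parent_id=gid, mutation_rate=rate)
                )

    depths = {g.id: rng.uniform(*depth_range) for g in genomes}
    return SyntheticCommunity(genomes, depths, seed)


@dataclass(frozen=True)
class RepeatSpec:
    """Controls breakpoint placement when fragmenting genomes into contigs.

    ``frags_per_genome`` bounds the number of fragments a linear genome is
    cut into (drawn uniformly). ``n_intra_repeat`` genomes receive a
    within-genome duplicated segment of length ``repeat_len`` whose two
    copies both become breakpoints, creating ambiguous (shared) end
    sequences. ``fragment_dtr`` controls whether circular DTR genomes are
    cut around the ring (producing an extended_circular case) or left as a
    single self-circular contig.
    """

    frags_per_genome: tuple[int, int] = (2, 5)
    min_fragment_len: int = 1_000
    n_intra_repeat: int = 0
    repeat_len: int = 150
    fragment_dtr: bool = False


def _linear_breakpoints(
    rng: random.Random, glen: int, n_frags: int, min_len: int
) -> list[int]:
    if n_frags < 2:
        return []
    for _ in range(200):
        pts = sorted(rng.sample(range(min_len, glen - min_len), n_frags - 1))
        gaps = [b - a for a, b in zip([0] + pts, pts + [glen])]
        if min(gaps) >= min_len:
            return pts
    return []  # genome too short to honour the spec; leave unfragmented


def fragment_at_repeats(
    community: SyntheticCommunity,
    L: int,
    repeat_spec: RepeatSpec = RepeatSpec(),
    seed: int = 0,
) -> tuple[ContigSet, list[TruthRecord]]:
    """Cut each genome into contigs whose flanks share exact L-length ends.

    A breakpoint at position p yields a left fragment ending with seq[p:p+L]
    and a right fragment starting with the same L-mer, emulating how de
    Bruijn assemblers terminate contigs at graph branchings. Optionally a
    duplicated segment is planted in some genomes first, with breakpoints at
    both copies, so repeat-adjacent ends share their L-mers across loci.
    Circular DTR genomes are either kept whole (single contig with its
    terminal repeat) or cut around the ring so the fragment chain closes.

    Truth records give every contig's genome of origin and coordinates.
    """
    rng = random.Random(seed)
    contigs = ContigSet()
    truth: list[TruthRecord] = []

    mutated_ids = {g.id for g in community.genomes if g.parent_id}
    intra_candidates = [
        g for g in community.genomes if not g.is_circular and g.id not in mutated_ids
    ]
    intra_ids = {
        g.id for g in rng.sample(intra_candidates, min(repeat_spec.n_intra_repeat, len(intra_candidates)))
    }

    # Parent genomes and their mutants share breakpoint positions, as real
    # assemblers break both subpopulations at the divergence-flanked loci.
    planned: dict[str, list[int]] = {}

    for genome in community.genomes:
        gid = genome.id
        seq = genome.seq
        glen = len(seq)

        if genome.is_circular:
            if not repeat_spec.fragment_dtr:
                contigs.add(Contig(f"{gid}_c0", seq))
                truth.append(TruthRecord(f"{gid}_c0", gid, 0, glen))
                continue
            # cut around the ring: every junction, incl. the wrap, shares L
            circle = seq[: genome.circle_len]
            m = len(circle)
            n_frags = rng.randint(*repeat_spec.frags_per_genome)
            n_frags = max(2, min(n_frags, m // max(repeat_spec.min_fragment_len, 2 * L)))
            pts = sorted(rng.sample(range(m), n_frags))
            ring = circle + circle  # for wrap-around slicing
            for j, p in enumerate(pts):
                q = pts[(j + 1) % n_frags] + (m if j == n_frags - 1 else 0)
                cid = f"{gid}_c{j}"
                contigs.add(Contig(cid, ring[p : q + L]))
                truth.append(TruthRecord(cid, gid, p, q + L))
            continue

        if genome.parent_id and genome.parent_id in planned:
            pts = [p for p in planned[genome.parent_id] if p < glen - repeat_spec.min_fragment_len]
        else:
            if gid in intra_ids and glen > 4 * repeat_spec.repeat_len + 4 * repeat_spec.min_fragment_len:
                r = repeat_spec.repeat_len
                third = glen // 3
                p1 = rng.randint(repeat_spec.min_fragment_len, third - r)
                p2 = rng.randint(2 * third, glen - repeat_spec.min_fragment_len - r)
                seq = seq[:p2] + seq[p1 : p1 + r] + seq[p2 + r :]
                pts = [p1, p2]
                # keep the community's genome in sync so read simulation
                # draws from the repeat-bearing sequence
                gi = next(i for i, g in enumerate(community.genomes) if g.id == gid)
                community.genomes[gi] = Genome(gid, seq)
            else:
                n_frags = rng.randint(*repeat_spec.frags_per_genome)
                pts = _linear_breakpoints(rng, glen, n_frags, repeat_spec.min_fragment_len)
            planned[gid] = pts

        bounds = [0] + pts + [glen]
        for j in range(len(bounds) - 1):
            start = bounds[j]
            end = min(bounds[j + 1] + L, glen) if j < len(bounds) - 2 else bounds[j + 1]
            cid = f"{gid}_c{j}"
            contigs.add(Contig(cid, seq[start:end]))
            truth.append(TruthRecord(cid, gid, start, end))

    return contigs, truth


@dataclass(frozen=True)
class _Placement:
    contig_id: str
    pos: int          # 0-based leftmost aligned position on the contig
    clip_left: int
    clip_right: int
    reverse: bool
    read_seq: str


def _place_read(
    gstart: int, gend: int, frags: list[TruthRecord], circle_len: int | None
) -> tuple[str, int, int, int] | None:
    """Pick the contig holding the largest part of genome interval [gstart, gend).

    Returns (contig_id, contig_pos, clip_left, clip_right) or None when the
    read falls entirely off every fragment (cannot happen on full tilings).
    """
    best = None
    for tr in frags:
        for shift in ((0,) if circle_len is None else (0, circle_len)):
            s, e = gstart + shift, gend + shift
            ov = min(e, tr.end) - max(s, tr.start)
            if ov <= 0:
                continue
            if best is None or ov > best[0]:
                clip_left = max(0, tr.start - s)
                clip_right = max(0, e - tr.end)
                best = (ov, tr.contig_id, max(s, tr.start) - tr.start, clip_left, clip_right)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


def simulate_reads(
    community: SyntheticCommunity,
    contigs: ContigSet,
    truth: list[TruthRecord],
    outdir: str | Path,
    read_len: int = 126,
    insert_mean: float = 350.0,
    insert_sd: float = 30.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Draw error-free 126 bp read pairs per genome at its depth and emit SAM + coverage.

    Pair count per genome is depth * genome_length / (2 * read_len). Inserts
    are Gaussian; fragments from circular genomes may cross the origin via
    the terminal-repeat representation. Alignments are written straight from
    the known coordinates with exact NM (0) tags and soft-clips where a read
    runs past its contig; the coverage table is computed from the same
    placements.
    """
    rng = random.Random(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    frags_by_genome: dict[str, list[TruthRecord]] = {}
    for tr in truth:
        frags_by_genome.setdefault(tr.genome_id, []).append(tr)

    ref_ids = contigs.ids()
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": cid, "LN": contigs[cid].length} for cid in ref_ids],
    }
    ref_index = {cid: i for i, cid in enumerate(ref_ids)}
    aligned_bases: dict[str, int] = {cid: 0 for cid in ref_ids}

    sam_path = outdir / "reads.sam"
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for genome in community.genomes:
            depth = community.depths[genome.id]
            glen = len(genome.seq)
            circle_len = genome.circle_len if genome.is_circular else None
            span = circle_len if genome.is_circular else glen
            n_pairs = round(depth * span / (2 * read_len))
            frags = frags_by_genome[genome.id]
            for p in range(n_pairs):
                insert = max(2 * read_len, round(rng.gauss(insert_mean, insert_sd)))
                insert = min(insert, glen)
                start = rng.randint(0, span - 1 if genome.is_circular else glen - insert)
                if start + insert > glen:  # linear genomes never enter here
                    start = rng.randint(0, glen - insert)
                r1 = (start, start + read_len)
                r2 = (start + insert - read_len, start + insert)
                placements = []
                for (gs, ge), reverse in ((r1, False), (r2, True)):
                    hit = _place_read(gs, ge, frags, circle_len)
                    if hit is None:
                        break
                    cid, pos, cl, cr = hit
                    raw = genome.seq[gs:ge]
                    placements.append(
                        _Placement(cid, pos, cl, cr, reverse,
                                   reverse_complement(raw) if reverse else raw)
                    )
                if len(placements) != 2:
                    continue
                qname = f"{genome.id}_p{p}"
                for k, pl in enumerate(placements):
                    mate = placements[1 - k]
                    a = pysam.AlignedSegment()
                    a.query_name = qname
                    a.query_sequence = pl.read_seq
                    a.flag = (
                        0x1 | 0x2
                        | (0x10 if pl.reverse else 0) | (0x20 if mate.reverse else 0)
                        | (0x40 if k == 0 else 0x80)
                    )
                    a.reference_id = ref_index[pl.contig_id]
                    a.reference_start = pl.pos
                    a.mapping_quality = 60
                    cigar = []
                    aligned = read_len - pl.clip_left - pl.clip_right
                    if pl.reverse:
                        # clips computed in genome space; flip for read orientation
                        left, right = pl.clip_right, pl.clip_left
                    else:
                        left, right = pl.clip_left, pl.clip_right
                    if left:
                        cigar.append((4, left))
                    cigar.append((0, aligned))
                    if right:
                        cigar.append((4, right))
                    a.cigartuples = cigar
                    a.next_reference_id = ref_index[mate.contig_id]
                    a.next_reference_start = mate.pos
                    a.template_length = 0
                    a.set_tag("NM", 0)
                    sam.write(a)
                    aligned_bases[pl.contig_id] += aligned

    cov_path = outdir / "coverage.tsv"
    with open(cov_path, "w") as fh:
        for cid in ref_ids:
            fh.write(f"{cid}\t{aligned_bases[cid] / contigs[cid].length:.4f}\n")

    contig_fa = outdir / "contigs.fasta"
    with open(contig_fa, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n{c.seq}\n")

    genome_fa = outdir / "genomes.fasta"
    with open(genome_fa, "w") as fh:
        for g in community.genomes:
            fh.write(f">{g.id}\n{g.seq}\n")

    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("contig_id\tgenome_id\tstart\tend\tstrand\n")
        for tr in truth:
            fh.write(f"{tr.contig_id}\t{tr.genome_id}\t{tr.start}\t{tr.end}\t{tr.strand}\n")

    return {
        "sam": sam_path,
        "coverage": cov_path,
        "contigs": contig_fa,
        "genomes": genome_fa,
        "truth": truth_path,
    }
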