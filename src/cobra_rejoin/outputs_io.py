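"""Write category FASTA files and summaries; post-process joins for gaps.

The gap check mirrors manual-curation practice: reads are remapped to the
joined sequences, alignments with more than the allowed mismatches are
discarded, and any stretch of a sequence left with zero mapped bases is
replaced by exactly ten Ns, flagging an unsupported region without
pretending to know its true length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from cobra_rejoin.join_engine import Category, ExtensionResult

CATEGORY_FILES = {
    Category.SELF_CIRCULAR: "self_circular.fasta",
    Category.EXTENDED_CIRCULAR: "extended_circular.fasta",
    Category.EXTENDED_PARTIAL: "extended_partial.fasta",
    Category.EXTENDED_FAILED: "extended_failed.fasta",
    Category.ORPHAN_END: "orphan_end.fasta",
}


def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def output_header(result: ExtensionResult) -> str:
    """Joined sequences get `<query>_extended[_circular]`; originals keep their id."""
    if result.category is Category.SELF_CIRCULAR:
        return f"{result.query_id}_self_circular"
    if result.category is Category.EXTENDED_CIRCULAR:
        return f"{result.query_id}_extended_circular"
    if result.category is Category.EXTENDED_PARTIAL:
        return f"{result.query_id}_extended"
    return result.query_id


def write_outputs(results: list[ExtensionResult], contigs, outdir: str | Path) -> dict[str, Path]:
    """Write the five per-category FASTA files plus TSV summary and joining detail.

    Failed and orphan queries are written with their original sequences so no
    query is dropped from the output set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    by_cat: dict[Category, list[ExtensionResult]] = {c: [] for c in Category}
    for r in results:
        by_cat[r.category].append(r)

    for cat, fname in CATEGORY_FILES.items():
        path = outdir / fname
        with open(path, "w") as fh:
            for r in by_cat[cat]:
                seq = r.joined_seq if r.joined_seq is not None else contigs[r.query_id].seq
                fh.write(f">{output_header(r)}\n{_wrap(seq)}\n")
        files[cat.value] = path

    summary = outdir / "joining_summary.tsv"
    with open(summary, "w") as fh:
        fh.write("query_id\tcategory\tjoined_id\tn_contigs_joined\tfinal_length\tmembers\n")
        for r in results:
            seq = r.joined_seq if r.joined_seq is not None else contigs[r.query_id].seq
            members = ",".join(str(oc) for oc in r.walk) or r.query_id
            fh.write(
                f"{r.query_id}\t{r.category.value}\t{output_header(r)}\t"
                f"{max(len(r.walk), 1)}\t{len(seq)}\t{members}\n"
            )
    files["summary"] = summary

    detail = outdir / "joining_detail.tsv"
    with open(detail, "w") as fh:
        fh.write("query_id\tposition\tcontig_id\torientation\n")
        for r in results:
            for pos, oc in enumerate(r.walk):
                fh.write(
                    f"{r.query_id}\t{pos}\t{oc.contig_id}\t{'+' if oc.forward else '-'}\n"
                )
    files["detail"] = detail
    return files


@dataclass(frozen=True)
class GapCheckParams:
    mm_max: int = 2
    gap_marker_len: int = 10

    def __post_init__(self) -> None:
        if self.gap_marker_len != 10:
            raise ValueError("gap marker is fixed at 10 Ns")


@dataclass(frozen=True)
class GapInterval:
    seq_id: str
    start: int  # 0-based, half-open
    end: int
    touches_edge: bool


def _read_mismatches(read) -> int | None:
    try:
        return read.get_tag("NM")
    except KeyError:
        return None


def gap_check(
    seqs: dict[str, str],
    alignment_path: str | Path,
    params: GapCheckParams = GapCheckParams(),
) -> tuple[dict[str, str], list[GapInterval]]:
    """Replace zero-coverage regions of each sequence with ten Ns.

    Per-base coverage is computed from primary mapped reads with at most
    ``mm_max`` mismatches (NM tag). Every maximal zero-coverage interval —
    including ones touching a sequence end, which are flagged — is replaced
    by exactly ``gap_marker_len`` Ns regardless of its true length.
    """
    path = str(alignment_path)
    mode = "rb" if path.endswith(".bam") else "r"
    depth: dict[str, np.ndarray] = {sid: np.zeros(len(s), dtype=np.int32) for sid, s in seqs.items()}

    with pysam.AlignmentFile(path, mode) as af:
        refs = set(af.references)
        missing = set(seqs) - refs
        if missing:
            raise KeyError(f"sequences absent from alignment header: {sorted(missing)}")
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            nm = _read_mismatches(read)
            if nm is None or nm > params.mm_max:
                continue
            ref = read.reference_name
            if ref not in depth:
                continue
            for start, end in read.get_blocks():
                depth[ref][start:end] += 1

    corrected: dict[str, str] = {}
    report: list[GapInterval] = []
    marker = "N" * params.gap_marker_len
    for sid, seq in seqs.items():
        cov = depth[sid]
        zero = cov == 0
        if not zero.any():
            corrected[sid] = seq
            continue
        # maximal runs of zero coverage
        boundaries = np.flatnonzero(np.diff(zero.astype(np.int8)))
        starts = [0] if zero[0] else []
        starts += [int(b) + 1 for b in boundaries if not zero[b]]
        ends = [int(b) + 1 for b in boundaries if zero[b]]
        if zero[-1]:
            ends.append(len(seq))
        pieces: list[str] = []
        prev = 0
        for s, e in zip(starts, ends):
            pieces.append(seq[prev:s])
            pieces.append(marker)
            report.append(GapInterval(sid, s, e, touches_edge=(s == 0 or e == len(seq))))
            prev = e
        pieces.append(seq[prev:])
        corrected[sid] = "".join(pieces)
    return corrected, report


def write_gap_report(report: list[GapInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\ttouches_edge\n")
        for g in report:
            fh.write(f"{g.seq_id}\t{g.start}\t{g.end}\t{int(g.touches_edge)}\n")
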