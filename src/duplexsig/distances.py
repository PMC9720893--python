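"""Signed end-distance classification of duplex alignments.

Each duplex end is classified relative to the *reference* strand:

* reference **overhang** — the reference extends beyond the query: negative
  distance (e.g. the canonical Dicer product has a negative 3' distance);
* reference **underhang** — the query extends beyond the reference:
  positive distance;
* **blunt** — neither strand extends: distance 0.

Distances are ``d5 = q_ext5 - ref_ext5`` and ``d3 = q_ext3 - ref_ext3``; at
each end at most one term is nonzero, so the distance is the signed length
of whichever strand protrudes.  Both ends are always reported: the joint
(d5, d3) pattern is what identifies a cleavage signature (e.g. a 5' 4-nt
and 3' 3-nt reference overhang, d5 = -4 / d3 = -3, for C. elegans 26G
siRNAs).

SAM interop uses standard minus-strand semantics: SEQ and CIGAR of a
reverse-strand record are stored in reference-forward orientation, so the
leading softclip is the query extension at the reference 5' end and the
trailing softclip the extension at the reference 3' end.  Only gapless
records (M/=/X/S operations) are meaningful for duplexes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

import pysam

from .align import DuplexAlignment, reverse_complement
from .io import ReadCollection

__all__ = [
    "EndDistances",
    "classify_end_distances",
    "distances_from_sam_record",
    "read_sam_duplexes",
    "write_sam",
]

EndType = Literal["overhang", "underhang", "blunt"]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _end_type(d: int) -> EndType:
    if d < 0:
        return "overhang"
    if d > 0:
        return "underhang"
    return "blunt"


@dataclass(frozen=True)
class EndDistances:
    """Signed 5' and 3' end distances of one duplex, reference-relative."""

    d5: int
    d3: int

    @property
    def type5(self) -> EndType:
        return _end_type(self.d5)

    @property
    def type3(self) -> EndType:
        return _end_type(self.d3)


def classify_end_distances(alignment: DuplexAlignment) -> EndDistances:
    """Convert a duplex alignment's end extensions into signed distances.

    ``d5 = q_ext5 - ref_ext5`` and ``d3 = q_ext3 - ref_ext3``; the duplex
    geometry guarantees at most one term per end is nonzero.  The sign fully
    determines the end type (negative: reference overhang; positive:
    underhang; zero: blunt), and ``ref_len - query_len == -(d5 + d3)``.
    """
    return EndDistances(
        d5=alignment.q_ext5 - alignment.ref_ext5,
        d3=alignment.q_ext3 - alignment.ref_ext3,
    )


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    pos = 0
    ops: list[tuple[int, str]] = []
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {cigar!r}")
        ops.append((int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(cigar) or not ops:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def distances_from_sam_record(
    cigar: str,
    pos: int,
    ref_len: int,
    query_len: int,
    reverse_strand: bool = True,
) -> EndDistances:
    """Classify end distances from a gapless SAM record's CIGAR and position.

    ``pos`` is the 0-based leftmost mapping position on the reference.  The
    record must be on the reverse strand (a duplex requires the query to
    align as its reverse complement); its stored orientation is
    reference-forward, so the leading softclip counts query bases beyond
    the reference 5' end.

    Raises
    ------
    ValueError
        For CIGARs containing I/D/N (gapped/spliced alignments are not
        duplexes), for forward-strand records, and for geometry that is not
        a valid duplex end (both strands extending at the same end).
    """
    if not reverse_strand:
        raise ValueError("forward-strand record: not a reverse-complement duplex")
    ops = _parse_cigar(cigar)
    if any(op in "IDN" for _, op in ops):
        raise ValueError(f"unsupported gapped/spliced CIGAR {cigar!r}")
    matched = sum(n for n, op in ops if op in "M=X")
    if matched == 0:
        raise ValueError(f"CIGAR {cigar!r} aligns no bases")
    lead = ops[0][1] == "S" and ops[0][0] or 0
    trail = len(ops) > 1 and ops[-1][1] == "S" and ops[-1][0] or 0
    clipped = sum(n for n, op in ops if op == "S")
    if clipped != lead + trail:
        raise ValueError(f"internal softclip in CIGAR {cigar!r}")
    if lead + matched + trail != query_len:
        raise ValueError(
            f"CIGAR {cigar!r} does not tile query of length {query_len}"
        )
    ref_ext5 = pos
    ref_ext3 = ref_len - (pos + matched)
    if ref_ext5 < 0 or ref_ext3 < 0:
        raise ValueError("alignment extends past the reference end")
    if (ref_ext5 > 0 and lead > 0) or (ref_ext3 > 0 and trail > 0):
        raise ValueError("both strands extend at one end: invalid duplex geometry")
    return EndDistances(d5=lead - ref_ext5, d3=trail - ref_ext3)


def write_sam(
    duplexes: list[DuplexAlignment],
    references: ReadCollection,
    queries: ReadCollection,
    path: str | Path,
) -> Path:
    """Export duplexes as a SAM/BAM file (format chosen by extension).

    Reference reads become the header's reference sequences; each duplex is
    one reverse-strand record whose SEQ is the reverse-complemented query
    (reference-forward orientation) with softclips encoding the end
    extensions (``<q_ext5>S<align_len>M<q_ext3>S``).
    """
    path = Path(path)
    ref_order = [r.read_id for r in references]
    ref_idx = {rid: i for i, rid in enumerate(ref_order)}
    ref_seqs = {r.read_id: r.sequence for r in references}
    q_seqs = {q.read_id: q.sequence for q in queries}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": rid, "LN": len(ref_seqs[rid])} for rid in ref_order
            ],
        }
    )
    mode = "wb" if path.suffix == ".bam" else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as fh:
        for d in sorted(duplexes, key=DuplexAlignment.sort_key):
            a = pysam.AlignedSegment(header)
            a.query_name = d.query_id
            a.flag = 16
            a.reference_id = ref_idx[d.ref_id]
            a.reference_start = d.align_start
            a.mapping_quality = 255
            cigar = []
            if d.q_ext5:
                cigar.append((pysam.CSOFT_CLIP, d.q_ext5))
            cigar.append((pysam.CMATCH, d.align_len))
            if d.q_ext3:
                cigar.append((pysam.CSOFT_CLIP, d.q_ext3))
            a.cigartuples = cigar
            a.query_sequence = reverse_complement(q_seqs[d.query_id])
            fh.write(a)
    return path


def read_sam_duplexes(
    path: str | Path,
) -> Iterator[tuple[DuplexAlignment, EndDistances]]:
    """Ingest a SAM/BAM of query-vs-reference alignments as duplexes.

    Gapless reverse-strand records are reconstructed into
    :class:`DuplexAlignment` / :class:`EndDistances` pairs; forward-strand
    and unmapped records are skipped with a warning, while gapped records
    raise (they cannot represent a base-paired duplex).
    """
    path = Path(path)
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                warnings.warn(f"skipping unmapped record {rec.query_name!r}")
                continue
            if not rec.is_reverse:
                warnings.warn(
                    f"skipping forward-strand record {rec.query_name!r}: "
                    "not a reverse-complement duplex"
                )
                continue
            cigar = rec.cigarstring or ""
            ref_len = fh.get_reference_length(rec.reference_name)
            query_len = rec.infer_read_length()
            dist = distances_from_sam_record(
                cigar, rec.reference_start, ref_len, query_len, reverse_strand=True
            )
            matched = sum(n for op, n in rec.cigartuples if op in (0, 7, 8))
            lead = rec.cigartuples[0][1] if rec.cigartuples[0][0] == 4 else 0
            trail = (
                rec.cigartuples[-1][1]
                if len(rec.cigartuples) > 1 and rec.cigartuples[-1][0] == 4
                else 0
            )
            aln = DuplexAlignment(
                ref_id=rec.reference_name,
                query_id=rec.query_name,
                ref_len=ref_len,
                query_len=query_len,
                align_start=rec.reference_start,
                align_len=matched,
                ref_ext5=rec.reference_start,
                ref_ext3=ref_len - (rec.reference_start + matched),
                q_ext5=lead,
                q_ext3=trail,
            )
            yield aln, dist
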