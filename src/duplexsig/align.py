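"""Reverse-complement ungapped alignment between two small-RNA read sets.

A Dicer-cleaved siRNA duplex consists of a guide (reference) strand and a
passenger (query) strand that are perfectly base-paired over their shared
span, with short single-stranded extensions at the ends (the cleavage
signature).  Finding candidate duplexes therefore reduces to sliding the
reverse complement of every query read along every reference read without
gaps, keeping placements whose overlapping span is an exact match of at
least ``min_overlap`` bases.  Unpaired terminal bases on either strand are
recorded as end extensions (the softclips of a local alignment).

Two engines implement the same acceptance rules:

* :func:`find_duplexes` — production path, k-mer-seeded so only plausible
  offsets are verified;
* :func:`brute_force_duplexes` — exhaustive offset scan, kept deliberately
  simple to serve as an independent oracle in tests.

All qualifying placements are reported, not a single best hit: small RNAs
multimap, and duplexes lost to best-hit arbitration are precisely the ones a
genome-based approach misses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

from .io import ReadCollection, SmallRNARead

__all__ = [
    "reverse_complement",
    "AlignmentParameters",
    "DuplexAlignment",
    "find_duplexes",
    "brute_force_duplexes",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Seed length cap for the k-mer index; the seed is min(min_overlap, this).
_MAX_SEED = 12


def reverse_complement(sequence: str) -> str:
    """Watson–Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters for reverse complement: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentParameters:
    """Tunable acceptance rules for duplex finding.

    min_overlap:
        Minimum number of paired bases; when None it defaults to the length
        of the shortest query read, so every query can in principle pair
        over its full length.
    max_mismatches:
        Mismatches tolerated inside the paired span (default 0: canonical
        duplexes only).  Extensions outside the span are never counted.
    """

    min_overlap: int | None = None
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.min_overlap is not None and self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class DuplexAlignment:
    """One reference–passenger pairing in reference coordinates.

    ``align_start`` is the 0-based start of the paired span on the
    reference; ``ref_ext5``/``ref_ext3`` are reference bases 5'/3' of the
    span, and ``q_ext5``/``q_ext3`` are bases of the reverse-complemented
    query protruding beyond the reference 5'/3' end.  The geometry is that
    of a duplex end: at each end at most one strand extends.
    """

    ref_id: str
    query_id: str
    ref_len: int
    query_len: int
    align_start: int
    align_len: int
    ref_ext5: int
    ref_ext3: int
    q_ext5: int
    q_ext3: int

    def __post_init__(self) -> None:
        if self.align_len < 1:
            raise ValueError("align_len must be >= 1")
        if self.ref_ext5 + self.align_len + self.ref_ext3 != self.ref_len:
            raise ValueError("reference extensions do not tile the reference")
        if self.q_ext5 + self.align_len + self.q_ext3 != self.query_len:
            raise ValueError("query extensions do not tile the query")
        if self.ref_ext5 != self.align_start:
            raise ValueError("align_start must equal ref_ext5")
        if (self.ref_ext5 > 0 and self.q_ext5 > 0) or (
            self.ref_ext3 > 0 and self.q_ext3 > 0
        ):
            raise ValueError("both strands extend at one end: invalid duplex geometry")

    def sort_key(self) -> tuple[str, str, int]:
        return (self.ref_id, self.query_id, self.align_start)


def _alignment_from_offset(
    ref: SmallRNARead, query: SmallRNARead, offset: int, align_len: int
) -> DuplexAlignment:
    """Build a DuplexAlignment for the placement of revcomp(query) at offset."""
    rlen, qlen = len(ref), len(query)
    start = max(0, offset)
    end = min(rlen, offset + qlen)
    return DuplexAlignment(
        ref_id=ref.read_id,
        query_id=query.read_id,
        ref_len=rlen,
        query_len=qlen,
        align_start=start,
        align_len=align_len,
        ref_ext5=start,
        ref_ext3=rlen - end,
        q_ext5=max(0, -offset),
        q_ext3=max(0, offset + qlen - rlen),
    )


def _accept_offset(
    ref_seq: str,
    rcq: str,
    offset: int,
    min_overlap: int,
    max_mismatches: int,
) -> int | None:
    """Return the span length if the placement qualifies, else None.

    The span is the full intersection of the placed query with the
    reference; with ``max_mismatches == 0`` it must match exactly.
    """
    rlen, qlen = len(ref_seq), len(rcq)
    start = max(0, offset)
    end = min(rlen, offset + qlen)
    span = end - start
    if span < min_overlap:
        return None
    a = ref_seq[start:end]
    b = rcq[start - offset : end - offset]
    if max_mismatches == 0:
        return span if a == b else None
    mm = sum(x != y for x, y in zip(a, b))
    return span if mm <= max_mismatches else None


def _is_self_identity(
    ref: SmallRNARead, query: SmallRNARead, offset: int, span: int
) -> bool:
    """Full-length placement of a read against itself.

    With zero mismatches such a placement only exists for sequences that are
    their own reverse complement (a legitimate palindromic duplex, kept);
    with mismatches allowed it is an artefact and is suppressed.
    """
    return (
        ref.read_id == query.read_id
        and offset == 0
        and span == len(ref) == len(query)
        and ref.sequence != reverse_complement(query.sequence)
    )


def _usable(reads: Iterable[SmallRNARead]) -> list[SmallRNARead]:
    # Reads containing N cannot satisfy zero-mismatch pairing; they stay in
    # the collection (and in library sizes) but are skipped here.
    return [r for r in reads if "N" not in r.sequence]


def _resolve_min_overlap(
    queries: ReadCollection, params: AlignmentParameters
) -> int:
    if params.min_overlap is not None:
        return params.min_overlap
    return queries.min_length()


def _check_inputs(references: ReadCollection, queries: ReadCollection) -> None:
    if len(references) == 0 or len(queries) == 0:
        raise ValueError("reference and query collections must be non-empty")


def brute_force_duplexes(
    references: ReadCollection,
    queries: ReadCollection,
    params: AlignmentParameters | None = None,
) -> list[DuplexAlignment]:
    """Exhaustive duplex enumeration: every pair at every ungapped offset.

    O(|A|·|B|·L²) and intended for small inputs; this is the reference
    oracle against which :func:`find_duplexes` is verified.  Output is in
    canonical (ref_id, query_id, align_start) order.
    """
    params = params or AlignmentParameters()
    _check_inputs(references, queries)
    min_overlap = _resolve_min_overlap(queries, params)
    out: list[DuplexAlignment] = []
    for ref in _usable(references):
        rseq = ref.sequence
        for q in _usable(queries):
            rcq = reverse_complement(q.sequence)
            qlen = len(rcq)
            for offset in range(-(qlen - min_overlap), len(rseq) - min_overlap + 1):
                span = _accept_offset(
                    rseq, rcq, offset, min_overlap, params.max_mismatches
                )
                if span is None or _is_self_identity(ref, q, offset, span):
                    continue
                out.append(_alignment_from_offset(ref, q, offset, span))
    out.sort(key=DuplexAlignment.sort_key)
    return out


class _KmerIndex:
    """Exact k-mer index over reference sequences for seeded placement."""

    def __init__(self, references: list[SmallRNARead], k: int):
        self.k = k
        self.refs = references
        self.table: dict[str, list[tuple[int, int]]] = {}
        for ri, ref in enumerate(references):
            s = ref.sequence
            for p in range(len(s) - k + 1):
                self.table.setdefault(s[p : p + k], []).append((ri, p))

    def candidate_offsets(self, rcq: str) -> Iterator[tuple[int, int]]:
        """Yield distinct (ref_index, offset) pairs sharing a k-mer with rcq."""
        seen: set[tuple[int, int]] = set()
        k = self.k
        for qp in range(len(rcq) - k + 1):
            for ri, p in self.table.get(rcq[qp : qp + k], ()):
                cand = (ri, p - qp)
                if cand not in seen:
                    seen.add(cand)
                    yield cand


def find_duplexes(
    references: ReadCollection,
    queries: ReadCollection,
    params: AlignmentParameters | None = None,
) -> list[DuplexAlignment]:
    """Enumerate all qualifying reference–query duplexes.

    A placement qualifies when the reverse complement of the query, slid
    ungapped along the reference, overlaps it by at least ``min_overlap``
    bases with at most ``max_mismatches`` mismatches inside the overlap
    (default 0).  Every qualifying offset of every pair is reported, in
    canonical (ref_id, query_id, align_start) order; when the two
    collections are the same file, mirrored pairs (a, b) and (b, a) are both
    reported.

    With zero mismatches any qualifying span of length >= min_overlap is an
    exact match, so a k-mer index over the references (seed length
    ``min(min_overlap, 12)``) finds every placement; candidates are then
    verified in full.  With mismatches allowed, seeds can be disrupted, so
    the exhaustive scan is used instead.
    """
    params = params or AlignmentParameters()
    _check_inputs(references, queries)
    min_overlap = _resolve_min_overlap(queries, params)
    usable_q = _usable(queries)
    if all(len(q) < min_overlap for q in usable_q):
        warnings.warn(
            f"min_overlap={min_overlap} exceeds every query length; "
            "no duplex can qualify",
            stacklevel=2,
        )
        return []
    if params.max_mismatches > 0:
        return brute_force_duplexes(references, queries, params)

    refs = _usable(references)
    index = _KmerIndex(refs, k=min(min_overlap, _MAX_SEED))
    out: list[DuplexAlignment] = []
    for q in usable_q:
        rcq = reverse_complement(q.sequence)
        for ri, offset in index.candidate_offsets(rcq):
            ref = refs[ri]
            span = _accept_offset(ref.sequence, rcq, offset, min_overlap, 0)
            if span is None or _is_self_identity(ref, q, offset, span):
                continue
            out.append(_alignment_from_offset(ref, q, offset, span))
    out.sort(key=DuplexAlignment.sort_key)
    return out
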