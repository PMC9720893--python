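"""Read ingest and library bookkeeping for small-RNA sequencing data.

Small-RNA duplex detection works directly on adapter-trimmed reads, so the
only I/O this package needs is FASTA in, FASTA/CSV out, plus the standard
library-preparation steps a small-RNA analysis applies before alignment:

* **collapsing** — merging identical sequences into one record that carries a
  copy count, so each distinct sequence is aligned once;
* **length filtering** — e.g. restricting candidate passenger strands to
  15–30 nt;
* **class filtering** — selecting an siRNA class defined by exact length and
  5' starting base (26G, 22G, 24-nt, ...);
* **RPM normalisation** — expressing class counts as reads per million.

Header convention: a trailing ``_<n>`` on a FASTA header is interpreted as a
copy count (the convention written by :func:`collapse_reads` and by common
collapse tools).  The full header, suffix included, remains the read id, so
parse → write → parse is stable.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

__all__ = [
    "SmallRNARead",
    "ReadCollection",
    "FastaParseError",
    "DuplicateHeaderError",
    "parse_fasta",
    "write_fasta",
    "collapse_reads",
    "filter_by_length",
    "filter_by_class",
    "rpm_normalize",
]

#: Nucleotide alphabet after ingest normalisation (U is rewritten to T).
ALLOWED_ALPHABET = frozenset("ACGTN")

_COUNT_SUFFIX = re.compile(r"_(\d+)$")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed; the message names the record."""


class DuplicateHeaderError(ValueError):
    """Raised when headers are not unique and auto-uniquing is disabled."""


@dataclass(frozen=True)
class SmallRNARead:
    """One small-RNA read: identifier, sequence and collapsed copy count.

    The sequence is stored in the DNA alphabet (U normalised to T on ingest)
    in the 5'→3' orientation of the sequenced strand.  ``count`` is the
    multiplicity of the sequence in the original library (1 for
    non-collapsed reads).
    """

    read_id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - ALLOWED_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: invalid characters {sorted(bad)} "
                f"(allowed: {''.join(sorted(ALLOWED_ALPHABET))})"
            )
        if self.count < 1:
            raise ValueError(f"read {self.read_id!r}: count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadCollection:
    """An ordered collection of reads from one input file.

    ``source_label`` records which role the file plays ("A" for reference /
    guide candidates, "B" for potential passengers, or anything else).
    """

    reads: list[SmallRNARead] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        ids = [r.read_id for r in self.reads]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise DuplicateHeaderError(f"duplicate read id {dup!r} in collection")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[SmallRNARead]:
        return iter(self.reads)

    def __getitem__(self, i: int) -> SmallRNARead:
        return self.reads[i]

    @property
    def library_size(self) -> int:
        """Total read multiplicity (sum of per-record counts)."""
        return sum(r.count for r in self.reads)

    def min_length(self) -> int:
        """Length of the shortest read; the default minimum-overlap source."""
        if not self.reads:
            raise ValueError("empty collection has no minimum length")
        return min(len(r) for r in self.reads)

    def by_id(self) -> dict[str, SmallRNARead]:
        return {r.read_id: r for r in self.reads}


def _normalize_sequence(raw: str, ordinal: int, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise FastaParseError(f"record {ordinal} ({rec_id!r}): empty sequence")
    bad = set(seq) - ALLOWED_ALPHABET
    if bad:
        raise FastaParseError(
            f"record {ordinal} ({rec_id!r}): invalid characters {sorted(bad)}"
        )
    return seq


def _count_from_header(header: str) -> int:
    m = _COUNT_SUFFIX.search(header)
    return int(m.group(1)) if m else 1


def parse_fasta(
    path: str | Path,
    auto_unique: bool = False,
    source_label: str = "",
    id_prefix: str = "read",
) -> ReadCollection:
    """Parse a FASTA file of small-RNA reads into a :class:`ReadCollection`.

    Sequences are uppercased and U→T normalised so RNA- and DNA-alphabet
    files are both accepted.  A trailing ``_<n>`` in the header is read as
    the copy count of the record (1 otherwise).

    Parameters
    ----------
    path:
        FASTA file, single- or multi-line records.
    auto_unique:
        When True, every header is replaced by a generated unique id of the
        form ``<id_prefix>_<ordinal>_<count>`` (count taken from the original
        header, so collapsing information survives re-headering).  When
        False, duplicate headers raise :class:`DuplicateHeaderError`.
    source_label:
        Stored on the returned collection ("A", "B", ...).
    id_prefix:
        Prefix for generated identifiers.

    Raises
    ------
    FastaParseError
        If the file is not FASTA or a record is malformed; the message names
        the 1-based record ordinal.
    DuplicateHeaderError
        On repeated headers with ``auto_unique=False``.
    """
    path = Path(path)
    reads: list[SmallRNARead] = []
    seen: set[str] = set()
    n = 0
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as err:
        raise FastaParseError(f"{path}: {err}") from err
    for rec in records:
        n += 1
        seq = _normalize_sequence(str(rec.seq), n, rec.id)
        count = _count_from_header(rec.id)
        if auto_unique:
            rid = f"{id_prefix}_{n}_{count}"
        else:
            rid = rec.id
            if rid in seen:
                raise DuplicateHeaderError(
                    f"duplicate header {rid!r} (record {n}); "
                    "re-run with auto_unique=True to assign fresh ids"
                )
            seen.add(rid)
        reads.append(SmallRNARead(rid, seq, count))
    if n == 0 and path.read_text().strip():
        raise FastaParseError(f"{path}: not FASTA-formatted (no records found)")
    return ReadCollection(reads, source_label=source_label)


def write_fasta(collection: ReadCollection, path: str | Path) -> Path:
    """Write a collection as single-line FASTA, one record per read."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in collection:
            fh.write(f">{r.read_id}\n{r.sequence}\n")
    return path


def collapse_reads(collection: ReadCollection) -> ReadCollection:
    """Merge identical sequences into single records carrying copy counts.

    One record is kept per distinct sequence, in order of first appearance;
    its count is the sum of the counts of the merged reads and its id is
    ``<seq-ordinal>_<count>`` (1-based ordinal).  Total multiplicity is
    conserved: ``library_size`` is unchanged.
    """
    totals: dict[str, int] = {}
    for r in collection:
        totals[r.sequence] = totals.get(r.sequence, 0) + r.count
    reads = [
        SmallRNARead(f"{i}_{c}", seq, c)
        for i, (seq, c) in enumerate(totals.items(), start=1)
    ]
    return ReadCollection(reads, source_label=collection.source_label)


def filter_by_length(
    collection: ReadCollection, min_len: int, max_len: int
) -> ReadCollection:
    """Retain reads with ``min_len <= length <= max_len`` (both inclusive)."""
    if not 1 <= min_len <= max_len:
        raise ValueError(f"invalid length bounds ({min_len}, {max_len})")
    kept = [r for r in collection if min_len <= len(r) <= max_len]
    return ReadCollection(kept, source_label=collection.source_label)


def filter_by_class(
    collection: ReadCollection, length: int, first_base: str | None = None
) -> ReadCollection:
    """Select an siRNA class by exact length and optional 5' starting base.

    E.g. ``length=26, first_base="G"`` selects the 26G class; with
    ``first_base=None`` all reads of the given length are kept.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if first_base is not None:
        first_base = first_base.upper().replace("U", "T")
        if first_base not in {"A", "C", "G", "T"}:
            raise ValueError(f"invalid first base {first_base!r}")
    kept = [
        r
        for r in collection
        if len(r) == length and (first_base is None or r.sequence[0] == first_base)
    ]
    return ReadCollection(kept, source_label=collection.source_label)


def rpm_normalize(
    counts: Mapping[object, float], library_size: int
) -> dict[object, float]:
    """Convert class counts to reads per million of the library.

    ``rpm = count / library_size * 1e6``.  Values sum to at most 1e6, with
    equality when the classes partition the library.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    for k, v in counts.items():
        if v < 0:
            raise ValueError(f"negative count for class {k!r}")
    return {k: v / library_size * 1e6 for k, v in counts.items()}
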