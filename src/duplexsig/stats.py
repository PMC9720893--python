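"""Aggregation and enrichment statistics for classified duplexes.

Counts of duplexes per signed end distance are tabulated in two modes:
``expression`` (each duplex weighted by its reference read's copy count, so
abundant guides dominate) and ``unique_reference`` (each distinct reference
sequence contributes at most once per distance class, a presence/absence
view).  Enrichment of a distance class is measured as the natural log of
its count over the mean count at that end, with a Wald z-score
``z = log_odds / sqrt(1/count + 1/mean)`` — the asymptotic standard error
of a log ratio of Poisson counts.  A one-sided cutoff of 1.645 (p = 0.05)
flags significant enrichment; depletion is reported but never flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .align import DuplexAlignment
from .distances import EndDistances
from .io import ReadCollection

__all__ = [
    "DistanceCountTable",
    "EnrichmentResult",
    "PassengerStats",
    "tally_distances",
    "passenger_statistics",
    "log_odds_z",
    "SIGNIFICANCE_CUTOFF",
]

#: One-sided z cutoff equivalent to p = 0.05.
SIGNIFICANCE_CUTOFF = 1.645

End = Literal["five_prime", "three_prime"]
TallyMode = Literal["expression", "unique_reference"]

ClassifiedDuplexes = Sequence[tuple[DuplexAlignment, EndDistances]]


@dataclass
class DistanceCountTable:
    """Duplex counts per signed end distance at one duplex end."""

    end: End
    counts: dict[int, int] = field(default_factory=dict)
    mode: TallyMode = "expression"


@dataclass(frozen=True)
class EnrichmentResult:
    """Log-odds enrichment of one distance class against the end's mean."""

    distance: int
    count: float
    log_odds: float
    z: float
    significant: bool


@dataclass
class PassengerStats:
    """Passenger-side summaries: per-reference counts, lengths, end types."""

    passengers_per_reference: dict[str, int] = field(default_factory=dict)
    passenger_length_histogram: dict[int, int] = field(default_factory=dict)
    overhang_type_summary: dict[End, dict[str, int]] = field(default_factory=dict)


def tally_distances(
    duplexes: ClassifiedDuplexes,
    mode: TallyMode = "expression",
    references: ReadCollection | None = None,
) -> tuple[DistanceCountTable, DistanceCountTable]:
    """Tabulate duplex counts per signed distance at the 5' and 3' ends.

    In ``expression`` mode each duplex contributes its reference read's
    multiplicity (1 when ``references`` is not given).  In
    ``unique_reference`` mode each distinct reference sequence counts at
    most once per distance class per end; without ``references`` the
    reference id stands in for its sequence.  Zero classes are absent.
    """
    if mode not in ("expression", "unique_reference"):
        raise ValueError(f"unknown tally mode {mode!r}")
    ref_counts: Mapping[str, int] = {}
    ref_seqs: Mapping[str, str] = {}
    if references is not None:
        ref_counts = {r.read_id: r.count for r in references}
        ref_seqs = {r.read_id: r.sequence for r in references}
    five = DistanceCountTable("five_prime", {}, mode)
    three = DistanceCountTable("three_prime", {}, mode)
    seen: set[tuple[str, str, int]] = set()
    for aln, dist in duplexes:
        for table, d in ((five, dist.d5), (three, dist.d3)):
            if mode == "expression":
                w = ref_counts.get(aln.ref_id, 1)
            else:
                key = (table.end, ref_seqs.get(aln.ref_id, aln.ref_id), d)
                if key in seen:
                    continue
                seen.add(key)
                w = 1
            table.counts[d] = table.counts.get(d, 0) + w
    return five, three


def passenger_statistics(duplexes: ClassifiedDuplexes) -> PassengerStats:
    """Summarise passengers: counts per reference, lengths, and end types.

    The length histogram counts one entry per duplex (its passenger's
    length), so the histogram total equals the number of passenger
    assignments; per-reference counts are over distinct passenger reads.
    """
    per_ref: dict[str, set[str]] = {}
    lengths: dict[int, int] = {}
    types: dict[End, dict[str, int]] = {}
    for aln, dist in duplexes:
        per_ref.setdefault(aln.ref_id, set()).add(aln.query_id)
        lengths[aln.query_len] = lengths.get(aln.query_len, 0) + 1
        for end, t in (("five_prime", dist.type5), ("three_prime", dist.type3)):
            types.setdefault(end, {})[t] = types.get(end, {}).get(t, 0) + 1
    return PassengerStats(
        passengers_per_reference={k: len(v) for k, v in per_ref.items()},
        passenger_length_histogram=lengths,
        overhang_type_summary=types,
    )


def log_odds_z(
    table: DistanceCountTable,
    cutoff: float = SIGNIFICANCE_CUTOFF,
    pseudocount: float = 0.0,
) -> list[EnrichmentResult]:
    """Per-class log-odds enrichment with Wald z-scores at one duplex end.

    The mean is the arithmetic mean of the counts over the classes present
    in the table.  For each class, ``log_odds = ln(count / mean)`` and
    ``z = log_odds / sqrt(1/count + 1/mean)``; a class is significant when
    z exceeds the one-sided cutoff.  Zero-count classes (possible only if a
    caller tabulated them explicitly, or pushed to positive by
    ``pseudocount``) get a -inf log-odds sentinel and are never
    significant.  Results are ordered by distance.
    """
    if not table.counts:
        raise ValueError("empty distance table")
    counts = {d: c + pseudocount for d, c in table.counts.items()}
    if all(c == 0 for c in counts.values()):
        raise ValueError("all-zero distance table")
    mean = sum(counts.values()) / len(counts)
    out = []
    for d in sorted(counts):
        c = counts[d]
        if c == 0:
            out.append(EnrichmentResult(d, c, -math.inf, -math.inf, False))
            continue
        lo = math.log(c / mean)
        z = lo / math.sqrt(1 / c + 1 / mean)
        out.append(EnrichmentResult(d, c, lo, z, z > cutoff))
    return out
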