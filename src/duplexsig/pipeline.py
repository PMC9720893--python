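"""End-to-end duplex-signature pipeline and its summary outputs.

``run_pipeline`` executes parse → (optional collapse) → duplex finding →
end-distance classification → tallies/enrichment, then writes five summary
CSVs and, optionally, per-distance-class alignment files:

1. ``<prefix>_overhang.csv`` — duplex counts per signed distance, both
   ends, expression-weighted, with enrichment columns;
2. ``<prefix>_unique_overhang.csv`` — same, counting each distinct
   reference sequence at most once per class;
3. ``<prefix>_passenger_number.csv`` — distinct passengers per reference;
4. ``<prefix>_passenger_length.csv`` — passenger length histogram;
5. ``<prefix>_overhang_type.csv`` — overhang/underhang/blunt totals per end.

All outputs are deterministic: identical inputs and configuration produce
byte-identical files.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rio
from .align import AlignmentParameters, DuplexAlignment, find_duplexes
from .distances import EndDistances, classify_end_distances, write_sam
from .stats import (
    DistanceCountTable,
    EnrichmentResult,
    PassengerStats,
    SIGNIFICANCE_CUTOFF,
    log_odds_z,
    passenger_statistics,
    tally_distances,
)

__all__ = ["RunConfig", "run_pipeline", "write_summary_csvs", "write_grouped_alignments"]

logger = logging.getLogger("duplexsig")

_END_LABEL = {"five_prime": "5p", "three_prime": "3p"}

OVERHANG_COLUMNS = ["end", "distance", "count", "log_odds", "z", "significant"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    ref_path: str | Path
    query_path: str | Path
    prefix: str
    out_dir: str | Path = "."
    auto_unique: bool = False
    collapse: bool = False
    min_overlap: int | None = None
    max_mismatches: int = 0
    write_alignments: bool = False
    force: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.prefix:
            raise ValueError("prefix must be non-empty")


def _enrichment_frame(
    tables: tuple[DistanceCountTable, DistanceCountTable],
    enrichment: dict[str, list[EnrichmentResult]],
) -> pd.DataFrame:
    rows = []
    for table in tables:
        res = {e.distance: e for e in enrichment.get(table.end, [])}
        for d in sorted(table.counts):
            e = res[d]
            rows.append(
                {
                    "end": _END_LABEL[table.end],
                    "distance": d,
                    "count": table.counts[d],
                    "log_odds": e.log_odds,
                    "z": e.z,
                    "significant": e.significant,
                }
            )
    return pd.DataFrame(rows, columns=OVERHANG_COLUMNS)


def _checked_path(out_dir: Path, name: str, force: bool) -> Path:
    p = out_dir / name
    if p.exists() and not force:
        raise FileExistsError(f"{p} exists; pass force=True (--force) to overwrite")
    return p


def write_summary_csvs(
    expression_tables: tuple[DistanceCountTable, DistanceCountTable],
    unique_tables: tuple[DistanceCountTable, DistanceCountTable],
    stats: PassengerStats,
    expression_enrichment: dict[str, list[EnrichmentResult]],
    unique_enrichment: dict[str, list[EnrichmentResult]],
    prefix: str,
    out_dir: str | Path,
    force: bool = False,
) -> dict[str, Path]:
    """Write the five summary CSVs; returns a name → path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for key, tables, enr in (
        ("overhang", expression_tables, expression_enrichment),
        ("unique_overhang", unique_tables, unique_enrichment),
    ):
        p = _checked_path(out_dir, f"{prefix}_{key}.csv", force)
        _enrichment_frame(tables, enr).to_csv(p, index=False)
        paths[key] = p

    p = _checked_path(out_dir, f"{prefix}_passenger_number.csv", force)
    pd.DataFrame(
        sorted(stats.passengers_per_reference.items()),
        columns=["ref_id", "n_passengers"],
    ).to_csv(p, index=False)
    paths["passenger_number"] = p

    p = _checked_path(out_dir, f"{prefix}_passenger_length.csv", force)
    pd.DataFrame(
        sorted(stats.passenger_length_histogram.items()),
        columns=["length", "count"],
    ).to_csv(p, index=False)
    paths["passenger_length"] = p

    p = _checked_path(out_dir, f"{prefix}_overhang_type.csv", force)
    rows = [
        {"end": _END_LABEL[end], "type": t, "count": c}
        for end in ("five_prime", "three_prime")
        for t, c in sorted(stats.overhang_type_summary.get(end, {}).items())
    ]
    pd.DataFrame(rows, columns=["end", "type", "count"]).to_csv(p, index=False)
    paths["overhang_type"] = p
    return paths


def write_grouped_alignments(
    classified: list[tuple[DuplexAlignment, EndDistances]],
    references: rio.ReadCollection,
    queries: rio.ReadCollection,
    prefix: str,
    out_dir: str | Path,
    fmt: str = "sam",
) -> dict[tuple[str, int], Path]:
    """Write one alignment file per observed (end, distance) class.

    Each duplex appears twice overall: once under its 5' class and once
    under its 3' class.  Re-ingesting a file reproduces its class label.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups: dict[tuple[str, int], list[DuplexAlignment]] = {}
    for aln, dist in classified:
        groups.setdefault(("five_prime", dist.d5), []).append(aln)
        groups.setdefault(("three_prime", dist.d3), []).append(aln)
    paths: dict[tuple[str, int], Path] = {}
    for (end, d), alns in sorted(groups.items()):
        p = out_dir / f"{prefix}_{_END_LABEL[end]}_{d}.{fmt}"
        write_sam(alns, references, queries, p)
        paths[(end, d)] = p
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Run the full duplex-signature analysis; returns a JSON-able summary.

    Zero duplexes is not an error: the five CSVs are written with header
    rows only and a warning is logged.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)

    file_a = rio.parse_fasta(
        config.ref_path, auto_unique=config.auto_unique, source_label="A", id_prefix="refA"
    )
    file_b = rio.parse_fasta(
        config.query_path, auto_unique=config.auto_unique, source_label="B", id_prefix="refB"
    )
    if config.collapse:
        file_a = rio.collapse_reads(file_a)
        file_b = rio.collapse_reads(file_b)
    logger.info("parsed %d reference reads, %d query reads", len(file_a), len(file_b))

    params = AlignmentParameters(
        min_overlap=config.min_overlap, max_mismatches=config.max_mismatches
    )
    duplexes = find_duplexes(file_a, file_b, params)
    classified = [(d, classify_end_distances(d)) for d in duplexes]
    logger.info("found %d duplexes", len(duplexes))
    if not duplexes:
        warnings.warn("no duplexes found; writing empty summary tables")

    expr = tally_distances(classified, "expression", references=file_a)
    uniq = tally_distances(classified, "unique_reference", references=file_a)
    stats = passenger_statistics(classified)

    def enrich(tables):
        return {
            t.end: (log_odds_z(t, cutoff=SIGNIFICANCE_CUTOFF) if t.counts else [])
            for t in tables
        }

    csvs = write_summary_csvs(
        expr, uniq, stats, enrich(expr), enrich(uniq),
        config.prefix, out_dir, force=config.force,
    )
    outputs = {k: str(v) for k, v in csvs.items()}

    if config.write_alignments and duplexes:
        grouped = write_grouped_alignments(
            classified, file_a, file_b, config.prefix, out_dir
        )
        outputs["alignments"] = {
            f"{_END_LABEL[end]}:{d}": str(p) for (end, d), p in grouped.items()
        }

    summary = {
        "n_reference_reads": len(file_a),
        "n_query_reads": len(file_b),
        "reference_library_size": file_a.library_size,
        "query_library_size": file_b.library_size,
        "n_duplexes": len(duplexes),
        "three_prime_counts": {str(k): v for k, v in sorted(expr[1].counts.items())},
        "five_prime_counts": {str(k): v for k, v in sorted(expr[0].counts.items())},
        "outputs": outputs,
    }
    logger.info("run summary: %s", json.dumps(summary))
    return summary
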