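"""Synthetic small-RNA datasets with planted duplexes of known geometry.

The generator emulates a small-RNA sequencing experiment reduced to its
duplex structure: a pool of random 21-nt reads, a subset of which are
"guide" references that each pair with one or more constructed passenger
strands realising a chosen signed (d5, d3) end-distance, the remainder
being background noise that pairs with nothing.  Because every planted
duplex is recorded in a truth table and background reads are
rejection-sampled against the reference set, pipeline recovery can be
checked exactly: the detector should report precisely the planted duplexes,
each with its planted distances.

Defaults reproduce the reference study conditions: 20,000 reads of 21 nt,
797 duplex-forming references, 1,365 planted duplexes whose 3' distance
distribution is {-4:40, -3:125, -2:550, -1:275, 0:200, +1:125, +2:25,
+3:25}, and 49% of duplexes flagged as multimapping (realised as duplicated
loci in the pseudo-genome; read-vs-read pairing is unaffected, which is the
property under test).  The 5' marginal is not pinned by the study
conditions; the default cycles d5 over {-2,-1,0,+1,+2} across duplexes,
keeping every passenger between 15 and 26 nt.

Spike-in generators build duplexes of fixed, known geometry to mix into any
dataset (synthetic or biological) as positive controls: either many copies
of one reference/passenger pair (expression-style) or many distinct random
references each with one passenger (unique-sequence style).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, NamedTuple

import numpy as np
import pandas as pd

from .align import _accept_offset, _KmerIndex, reverse_complement
from .io import ReadCollection, SmallRNARead

__all__ = [
    "SimulationConfig",
    "SpikeInConfig",
    "TruthRow",
    "TruthTable",
    "SimulatedDataset",
    "DEFAULT_THREE_PRIME_SPEC",
    "DEFAULT_FIVE_PRIME_CYCLE",
    "default_distance_spec",
    "simulate_dataset",
    "build_simulated_genome",
    "make_spikein",
]

#: Planted 3' distance distribution of the default simulation
#: (distance -> duplex count; total 1365).
DEFAULT_THREE_PRIME_SPEC: tuple[tuple[int, int], ...] = (
    (-4, 40),
    (-3, 125),
    (-2, 550),
    (-1, 275),
    (0, 200),
    (1, 125),
    (2, 25),
    (3, 25),
)

#: Default 5' distances, cycled across the duplexes of each 3' class.
DEFAULT_FIVE_PRIME_CYCLE: tuple[int, ...] = (-2, -1, 0, 1, 2)

_BASES = "ACGT"


def default_distance_spec() -> list[tuple[int, int, int]]:
    """Joint (d5, d3, count) triples realising the default marginals.

    Each 3' class's count is split as evenly as possible over the 5'
    cycle, remainders going to the leading cycle entries; the result is
    deterministic and sums to 1365.
    """
    spec: list[tuple[int, int, int]] = []
    k = len(DEFAULT_FIVE_PRIME_CYCLE)
    for d3, count in DEFAULT_THREE_PRIME_SPEC:
        base, rem = divmod(count, k)
        for i, d5 in enumerate(DEFAULT_FIVE_PRIME_CYCLE):
            c = base + (1 if i < rem else 0)
            if c > 0:
                spec.append((d5, d3, c))
    return spec


class TruthRow(NamedTuple):
    ref_id: str
    query_id: str
    d5: int
    d3: int


@dataclass
class TruthTable:
    """Ground truth: one row per planted duplex."""

    rows: list[TruthRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[TruthRow]:
        return iter(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["ref_id", "query_id", "d5", "d3"])

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        return cls([TruthRow(r.ref_id, r.query_id, int(r.d5), int(r.d3)) for r in df.itertuples()])


@dataclass
class SimulationConfig:
    """Study conditions for the planted-duplex simulation (see module doc)."""

    n_total_reads: int = 20_000
    read_len: int = 21
    n_duplex_refs: int = 797
    distance_spec: list[tuple[int, int, int]] | None = None
    multimap_fraction: float = 0.49
    seed: int = 0

    def resolved_spec(self) -> list[tuple[int, int, int]]:
        spec = self.distance_spec if self.distance_spec is not None else default_distance_spec()
        for d5, d3, c in spec:
            if c < 0:
                raise ValueError("distance_spec counts must be >= 0")
            if self.read_len + d5 + d3 < 1:
                raise ValueError(
                    f"distance_spec entry (d5={d5}, d3={d3}) implies a passenger "
                    f"of length {self.read_len + d5 + d3} <= 0"
                )
            if self.read_len - max(-d5, 0) - max(-d3, 0) < 1:
                raise ValueError(
                    f"distance_spec entry (d5={d5}, d3={d3}) leaves no paired span"
                )
        return spec

    def validate(self) -> None:
        if self.read_len < 1 or self.n_total_reads < 1:
            raise ValueError("read_len and n_total_reads must be positive")
        if not 0 <= self.n_duplex_refs <= self.n_total_reads:
            raise ValueError("n_duplex_refs must be within [0, n_total_reads]")
        if not 0.0 <= self.multimap_fraction <= 1.0:
            raise ValueError("multimap_fraction must be in [0, 1]")
        total = sum(c for _, _, c in self.resolved_spec())
        if total < self.n_duplex_refs:
            raise ValueError(
                "planted duplex total must be >= n_duplex_refs "
                "(every reference forms at least one duplex)"
            )


@dataclass
class SimulatedDataset:
    """Simulation output: File A, File B, truth, and multimap locus copies."""

    file_a: ReadCollection
    file_b: ReadCollection
    truth: TruthTable
    multimap_copies: dict[str, int] = field(default_factory=dict)
    min_overlap: int = 0

    def __iter__(self):
        # allow fileA, fileB, truth = simulate_dataset(...)
        return iter((self.file_a, self.file_b, self.truth))


def _random_seq_batch(rng: np.random.Generator, n: int, length: int) -> list[str]:
    arr = rng.integers(0, 4, size=(n, length))
    return ["".join(_BASES[b] for b in row) for row in arr]


def _draw_distinct(
    rng: np.random.Generator, n: int, length: int, used: set[str]
) -> list[str]:
    """Draw n random sequences distinct from each other and from ``used``."""
    out: list[str] = []
    while len(out) < n:
        for s in _random_seq_batch(rng, n - len(out), length):
            if s not in used:
                used.add(s)
                out.append(s)
    return out


def _build_passenger(
    rng: np.random.Generator, ref_seq: str, d5: int, d3: int
) -> tuple[str, int]:
    """Construct a passenger realising (d5, d3); returns (sequence, offset).

    The offset is where the reverse-complemented passenger starts on the
    reference (negative when the passenger protrudes past the 5' end).
    """
    ref_ext5, q_ext5 = max(-d5, 0), max(d5, 0)
    ref_ext3, q_ext3 = max(-d3, 0), max(d3, 0)
    core = ref_seq[ref_ext5 : len(ref_seq) - ref_ext3]
    left = "".join(_BASES[b] for b in rng.integers(0, 4, size=q_ext5))
    right = "".join(_BASES[b] for b in rng.integers(0, 4, size=q_ext3))
    rcq = left + core + right
    return reverse_complement(rcq), ref_ext5 - q_ext5


def _placements(
    index: _KmerIndex, rcq: str, min_overlap: int
) -> set[tuple[int, int]]:
    """All accepted (ref_index, offset) zero-mismatch placements of rcq."""
    hits: set[tuple[int, int]] = set()
    for ri, off in index.candidate_offsets(rcq):
        if _accept_offset(index.refs[ri].sequence, rcq, off, min_overlap, 0) is not None:
            hits.add((ri, off))
    return hits


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate File A / File B / truth for a planted-duplex experiment.

    File A holds the duplex-forming reference reads; File B holds every
    planted passenger followed by ``n_total_reads - n_duplex_refs``
    background reads.  Construction guarantees exact recovery under the
    detector's default settings:

    * duplexes are distributed round-robin over the references, so every
      reference owns at least one;
    * each passenger is verified to place at exactly its planted offset
      against the whole reference set (random extension bases, then the
      colliding reference, are re-drawn on the vanishingly rare collision);
    * background reads are rejection-sampled so none forms a qualifying
      duplex with any reference.

    Fully deterministic for a given config (seeded numpy generator).
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    spec = config.resolved_spec()
    planted = [(d5, d3) for d5, d3, c in spec for _ in range(c)]
    n_duplex = len(planted)
    n_refs = config.n_duplex_refs
    n_background = config.n_total_reads - n_refs

    min_pass_len = min(config.read_len + d5 + d3 for d5, d3 in planted)
    min_overlap = min(config.read_len, min_pass_len) if n_background else min_pass_len

    used: set[str] = set()
    ref_seqs = _draw_distinct(rng, n_refs, config.read_len, used)
    owner = [j % n_refs for j in range(n_duplex)]

    k = min(min_overlap, 12)
    pass_seqs: list[str | None] = [None] * n_duplex
    expected: list[tuple[int, int] | None] = [None] * n_duplex

    def make_refs() -> list[SmallRNARead]:
        return [
            SmallRNARead(f"ref{i + 1}", s) for i, s in enumerate(ref_seqs)
        ]

    for _round in range(20):
        refs = make_refs()
        index = _KmerIndex(refs, k)
        for j, (d5, d3) in enumerate(planted):
            if pass_seqs[j] is None:
                seq, off = _build_passenger(rng, ref_seqs[owner[j]], d5, d3)
                pass_seqs[j] = seq
                expected[j] = (owner[j], off)
        bad_refs: set[int] = set()
        for j in range(n_duplex):
            want = {expected[j]}
            for _try in range(10):
                hits = _placements(index, reverse_complement(pass_seqs[j]), min_overlap)
                if hits == want:
                    break
                d5, d3 = planted[j]
                if max(d5, 0) + max(d3, 0) == 0:
                    # no random bases to redraw: a reference-level collision
                    bad_refs.update(ri for ri, _ in hits - want)
                    if not bad_refs:
                        bad_refs.add(owner[j])
                    break
                seq, off = _build_passenger(rng, ref_seqs[owner[j]], d5, d3)
                pass_seqs[j] = seq
                expected[j] = (owner[j], off)
            else:
                hits = _placements(index, reverse_complement(pass_seqs[j]), min_overlap)
                bad_refs.update(ri for ri, _ in hits - {expected[j]})
                if not bad_refs:
                    bad_refs.add(owner[j])
        if not bad_refs:
            break
        for ri in bad_refs:
            ref_seqs[ri] = _draw_distinct(rng, 1, config.read_len, used)[0]
            for j in range(n_duplex):
                if owner[j] == ri:
                    pass_seqs[j] = None
    else:
        raise RuntimeError("could not realise a collision-free simulation")

    refs = make_refs()
    index = _KmerIndex(refs, k)
    passengers = [
        SmallRNARead(f"pass{j + 1}", pass_seqs[j]) for j in range(n_duplex)
    ]
    truth = TruthTable(
        [
            TruthRow(refs[owner[j]].read_id, passengers[j].read_id, d5, d3)
            for j, (d5, d3) in enumerate(planted)
        ]
    )

    background: list[SmallRNARead] = []
    while len(background) < n_background:
        for s in _draw_distinct(rng, n_background - len(background), config.read_len, used):
            if _placements(index, reverse_complement(s), min_overlap):
                used.discard(s)
                continue
            background.append(SmallRNARead(f"bg{len(background) + 1}", s))

    file_a = ReadCollection(refs, source_label="A")
    file_b = ReadCollection(passengers + background, source_label="B")

    n_multi = int(round(config.multimap_fraction * n_duplex))
    multi_idx = rng.choice(n_duplex, size=n_multi, replace=False) if n_multi else []
    copies: dict[str, int] = {}
    for j in sorted(int(i) for i in multi_idx):
        n_copies = int(rng.integers(2, 7))  # 2-6 genomic loci
        copies[truth.rows[j].ref_id] = n_copies
        copies[truth.rows[j].query_id] = n_copies

    return SimulatedDataset(file_a, file_b, truth, copies, min_overlap)


def build_simulated_genome(
    file_a: ReadCollection,
    file_b: ReadCollection,
    seed: int = 0,
    copies: dict[str, int] | None = None,
) -> str:
    """Concatenate all reads into a single pseudo-genome sequence.

    Layout: every File A read then every File B read, each repeated
    ``copies[read_id]`` times (default 1, used to plant multimapping loci),
    joined by 5 random nucleotides between consecutive segments.  Length is
    therefore ``sum(len * copies) + 5 * (n_segments - 1)``; the empty input
    yields an empty genome.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    copies = copies or {}
    segments = [
        r.sequence
        for coll in (file_a, file_b)
        for r in coll
        for _ in range(copies.get(r.read_id, 1))
    ]
    if not segments:
        return ""
    parts = [segments[0]]
    for seg in segments[1:]:
        parts.append("".join(_BASES[b] for b in rng.integers(0, 4, size=5)))
        parts.append(seg)
    return "".join(parts)


@dataclass
class SpikeInConfig:
    """Geometry of a spike-in control duplex set.

    ``single_reference`` mode replicates one template read ``n_spikes``
    times with identical passengers (expression-style spike-in;
    e.g. a 26-nt guide with d5=0, d3=-1 gives the canonical 25-nt
    passenger, a 22-nt guide with d5=d3=-2 an 18-nt passenger).
    ``variable_reference`` mode draws ``n_spikes`` distinct random
    references of ``ref_len`` (optionally starting with ``first_base``),
    each with one passenger; the default geometry (d5=-1, d3=-2) on 24-nt
    references gives 21-nt passengers.
    """

    mode: Literal["single_reference", "variable_reference"] = "variable_reference"
    n_spikes: int = 5000
    ref_len: int | None = 24
    first_base: str | None = None
    d5: int = -1
    d3: int = -2
    seed: int = 0


def make_spikein(
    config: SpikeInConfig, template: SmallRNARead | None = None
) -> tuple[ReadCollection, ReadCollection, TruthTable]:
    """Generate spike-in references, passengers and their truth table."""
    rng = np.random.default_rng(config.seed)
    if config.n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")

    if config.mode == "single_reference":
        if template is None:
            raise ValueError("single_reference mode requires a template read")
        ref_seq_list = [template.sequence] * config.n_spikes
    elif config.mode == "variable_reference":
        if config.ref_len is None:
            raise ValueError("variable_reference mode requires ref_len")
        first = config.first_base.upper().replace("U", "T") if config.first_base else None
        used: set[str] = set()
        ref_seq_list = []
        while len(ref_seq_list) < config.n_spikes:
            for s in _random_seq_batch(rng, config.n_spikes - len(ref_seq_list), config.ref_len):
                if first is not None:
                    s = first + s[1:]
                if s in used:
                    continue
                used.add(s)
                ref_seq_list.append(s)
    else:
        raise ValueError(f"unknown spike-in mode {config.mode!r}")

    ref_len = len(ref_seq_list[0])
    if ref_len + config.d5 + config.d3 < 1:
        raise ValueError("spike geometry implies a passenger of length <= 0")
    if ref_len - max(-config.d5, 0) - max(-config.d3, 0) < 1:
        raise ValueError("spike geometry leaves no paired span")

    if config.mode == "single_reference":
        # one construction shared by all spikes: identical passengers
        seq, _ = _build_passenger(rng, ref_seq_list[0], config.d5, config.d3)
        pass_seq_list = [seq] * config.n_spikes
    else:
        pass_seq_list = [
            _build_passenger(rng, rs, config.d5, config.d3)[0] for rs in ref_seq_list
        ]

    refs = ReadCollection(
        [SmallRNARead(f"spikeref{i + 1}", s) for i, s in enumerate(ref_seq_list)],
        source_label="spike_A",
    )
    passengers = ReadCollection(
        [SmallRNARead(f"spikepass{i + 1}", s) for i, s in enumerate(pass_seq_list)],
        source_label="spike_B",
    )
    truth = TruthTable(
        [
            TruthRow(r.read_id, p.read_id, config.d5, config.d3)
            for r, p in zip(refs, passengers)
        ]
    )
    return refs, passengers, truth
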