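"""Planted-duplex simulator, pseudo-genome builder and spike-in generator."""

import pytest

from duplexsig import (
    SimulationConfig,
    SmallRNARead,
    SpikeInConfig,
    build_simulated_genome,
    make_spikein,
    reverse_complement,
    simulate_dataset,
    write_fasta,
)
from duplexsig.io import ReadCollection
from duplexsig.simulate import TruthTable, default_distance_spec


class TestDefaultSpec:
    def test_totals_and_marginals(self):
        spec = default_distance_spec()
        assert sum(c for _, _, c in spec) == 1365
        three = {}
        for d5, d3, c in spec:
            three[d3] = three.get(d3, 0) + c
        assert three == {-4: 40, -3: 125, -2: 550, -1: 275, 0: 200, 1: 125, 2: 25, 3: 25}


class TestSimulateDataset:
    def test_small_bookkeeping(self):
        ds = simulate_dataset(
            SimulationConfig(
                n_total_reads=10, n_duplex_refs=2, distance_spec=[(0, 0, 2)], seed=5
            )
        )
        assert len(ds.truth) == 2
        assert len(ds.file_a) == 2
        assert len(ds.file_b) == 2 + 8
        # a blunt duplex's passenger is the exact reverse complement
        seqs_a = {r.read_id: r.sequence for r in ds.file_a}
        seqs_b = {r.read_id: r.sequence for r in ds.file_b}
        for row in ds.truth:
            assert seqs_b[row.query_id] == reverse_complement(seqs_a[row.ref_id])

    def test_deterministic_fasta_output(self, tmp_path):
        cfg = dict(n_total_reads=120, n_duplex_refs=10,
                   distance_spec=[(-1, -2, 10), (0, 0, 5)], seed=9)
        for run in ("x", "y"):
            ds = simulate_dataset(SimulationConfig(**cfg))
            write_fasta(ds.file_a, tmp_path / f"{run}_A.fa")
            write_fasta(ds.file_b, tmp_path / f"{run}_B.fa")
        assert (tmp_path / "x_A.fa").read_bytes() == (tmp_path / "y_A.fa").read_bytes()
        assert (tmp_path / "x_B.fa").read_bytes() == (tmp_path / "y_B.fa").read_bytes()

    def test_passenger_lengths_match_planted_distances(self, small_sim):
        seqs_b = {r.read_id: r.sequence for r in small_sim.file_b}
        read_len = 21
        for row in small_sim.truth:
            assert len(seqs_b[row.query_id]) == read_len + row.d5 + row.d3

    def test_multimap_copies_cover_requested_fraction(self, small_sim):
        n_multi = sum(
            1 for row in small_sim.truth if row.query_id in small_sim.multimap_copies
        )
        assert n_multi == round(0.49 * len(small_sim.truth))
        assert all(2 <= c <= 6 for c in small_sim.multimap_copies.values())

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="passenger"):
            simulate_dataset(
                SimulationConfig(
                    n_total_reads=10, n_duplex_refs=1, distance_spec=[(-11, -11, 1)],
                    read_len=21,
                )
            )

    def test_truth_tsv_round_trip(self, tmp_path, small_sim):
        path = small_sim.truth.write_tsv(tmp_path / "truth.tsv")
        back = TruthTable.read_tsv(path)
        assert back.rows == small_sim.truth.rows


class TestGenomeBuilder:
    def test_length_arithmetic(self):
        reads = ReadCollection(
            [SmallRNARead("a", "A" * 21), SmallRNARead("b", "C" * 21)]
        )
        genome = build_simulated_genome(reads, ReadCollection([]), seed=1)
        assert len(genome) == 2 * 21 + 5

    def test_empty_input(self):
        empty = ReadCollection([])
        assert build_simulated_genome(empty, empty, seed=1) == ""

    def test_deterministic(self):
        reads = ReadCollection([SmallRNARead("a", "ACGTACGT")])
        g1 = build_simulated_genome(reads, ReadCollection([]), seed=7)
        g2 = build_simulated_genome(reads, ReadCollection([]), seed=7)
        assert g1 == g2

    def test_copies_plant_multimapping_loci(self):
        reads = ReadCollection([SmallRNARead("a", "A" * 10), SmallRNARead("b", "C" * 10)])
        genome = build_simulated_genome(
            reads, ReadCollection([]), seed=1, copies={"a": 3}
        )
        assert len(genome) == 4 * 10 + 3 * 5
        assert genome.count("A" * 10) >= 3


class TestSpikeIn:
    def test_single_reference_22G_geometry(self):
        template = SmallRNARead("t22", "G" + "ACGTACGTACGTACGTACGTA")
        assert len(template.sequence) == 22
        refs, passengers, truth = make_spikein(
            SpikeInConfig(mode="single_reference", n_spikes=50, d5=-2, d3=-2, seed=2),
            template=template,
        )
        assert len(refs) == len(passengers) == len(truth) == 50
        assert {r.sequence for r in refs} == {template.sequence}
        pass_seqs = {p.sequence for p in passengers}
        assert len(pass_seqs) == 1
        assert len(next(iter(pass_seqs))) == 18

    def test_single_reference_26G_geometry(self):
        template = SmallRNARead("t26", "G" + "ACGTC" * 5)
        assert len(template.sequence) == 26
        _, passengers, _ = make_spikein(
            SpikeInConfig(mode="single_reference", n_spikes=10, d5=0, d3=-1, seed=2),
            template=template,
        )
        assert all(len(p.sequence) == 25 for p in passengers)

    def test_variable_reference_24C(self):
        refs, passengers, truth = make_spikein(
            SpikeInConfig(
                mode="variable_reference", n_spikes=200, ref_len=24,
                first_base="C", d5=-1, d3=-2, seed=4,
            )
        )
        assert len({r.sequence for r in refs}) == 200
        assert all(r.sequence.startswith("C") and len(r.sequence) == 24 for r in refs)
        assert all(len(p.sequence) == 21 for p in passengers)
        assert all((row.d5, row.d3) == (-1, -2) for row in truth)

    def test_blunt_spike_is_exact_reverse_complement(self):
        refs, passengers, _ = make_spikein(
            SpikeInConfig(mode="variable_reference", n_spikes=1, ref_len=24, d5=0, d3=0, seed=1)
        )
        assert passengers[0].sequence == reverse_complement(refs[0].sequence)

    def test_template_required_for_single_reference(self):
        with pytest.raises(ValueError, match="template"):
            make_spikein(SpikeInConfig(mode="single_reference", n_spikes=5))

    def test_unrealizable_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_spikein(
                SpikeInConfig(mode="variable_reference", n_spikes=5, ref_len=10, d5=-6, d3=-6)
            )
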