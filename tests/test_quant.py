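"""K-mer transcript assignment, UMI deduplication, matrix I/O, saturation."""

import numpy as np
import pandas as pd
import pytest

from cbtiseq.demux import DemuxConfig, demultiplex_stream
from cbtiseq.quant import (
    ASSIGNMENT_COLUMNS,
    MAPPED,
    ExpressionMatrix,
    assign_reads,
    assign_transcript,
    build_kmer_index,
    count_umis,
    downsample_saturation,
    read_matrix,
    read_matrix_tsv,
    write_matrix,
    write_matrix_tsv,
)
from cbtiseq.simulate import (
    SimConfig,
    Transcriptome,
    TranscriptRecord,
    make_transcriptome,
    simulate_library,
)


@pytest.fixture(scope="module")
def index(transcriptome):
    return build_kmer_index(transcriptome, k=21)


class TestKmerIndex:
    def test_forward_kmer_count_single_transcript(self):
        t = make_transcriptome(1, mean_length=200, sd_length=0, min_length=200, seed=1)
        idx = build_kmer_index(t, k=21)
        n_positions = sum(len(v) for v in idx.lookup.values())
        assert n_positions == 200 - 21 + 1

    def test_k_exceeding_transcript_errors(self):
        t = make_transcriptome(1, mean_length=200, sd_length=0, min_length=200, seed=1)
        with pytest.raises(ValueError):
            build_kmer_index(t, k=300)

    def test_spot_check_entries_against_sequence(self, transcriptome, index):
        """Random entries must occur verbatim at the stated offset."""
        rng = np.random.default_rng(0)
        kmers = list(index.lookup)
        seqs = {r.transcript_id: r.sequence for r in transcriptome.records}
        for km in (kmers[i] for i in rng.integers(0, len(kmers), 100)):
            for t_idx, off in index.lookup[km]:
                tid = index.transcript_ids[t_idx]
                assert seqs[tid][off : off + 21] == km


class TestAssign:
    def test_exact_substring_maps_with_position(self, transcriptome, index):
        rec = transcriptome.records[4]
        insert = rec.sequence[40:140]
        status, gene, transcript, strand, start, end = assign_transcript(insert, index)
        assert status == MAPPED and gene == rec.gene_id
        assert transcript == rec.transcript_id
        assert (strand, start, end) == ("+", 40, 140)

    def test_reverse_strand_substring(self, transcriptome, index):
        from cbtiseq.seqs import revcomp

        rec = transcriptome.records[7]
        insert = revcomp(rec.sequence[100:200])
        status, gene, _, strand, start, end = assign_transcript(insert, index)
        assert status == MAPPED and gene == rec.gene_id
        assert (strand, start, end) == ("-", 100, 200)

    def test_identical_transcripts_ambiguous(self):
        seq = make_transcriptome(1, mean_length=500, sd_length=0, seed=2).records[0].sequence
        twins = Transcriptome((
            TranscriptRecord("G1", "G1.T1", seq),
            TranscriptRecord("G2", "G2.T1", seq),
        ))
        idx = build_kmer_index(twins)
        status, *_ = assign_transcript(seq[50:150], idx)
        assert status == "ambiguous"

    def test_short_insert_too_short(self, index):
        status, *_ = assign_transcript("ACGTACGT", index)
        assert status == "too_short"

    def test_errorfree_round_trip_transcript_and_coordinate(self, set_a, set_b):
        """With no errors, no poly(A) and no trimming, every sufficiently
        long decoded insert maps to its ground-truth transcript with the
        correct B-proximal fragment coordinate."""
        t = make_transcriptome(15, seed=50)
        from cbtiseq.barcodes import SampleSheet

        sheet = SampleSheet.diagonal(3)
        cfg = SimConfig(reads_per_sample=1000, polya_length=0, seed=51)
        pairs, truth = simulate_library(t, sheet, set_a, set_b, cfg)
        records, _ = demultiplex_stream(
            pairs, set_a, set_b, sheet, DemuxConfig(trim_polya=False)
        )
        idx = build_kmer_index(t)
        asn = assign_reads(records, idx).set_index("read_id")
        truth = truth.set_index("read_id")
        checked = 0
        for read_id, row in asn.iterrows():
            tr = truth.loc[read_id]
            if row.status != MAPPED:
                # only tolerated for inserts below twice the k-mer size
                assert (tr.frag_end - tr.frag_start) < 42
                continue
            assert row.gene_id == tr.gene_id
            assert row.transcript_id == tr.transcript_id
            if tr.orientation == "A_left":  # B adapter on the 3' fragment end
                assert row.strand == "-" and row.end == tr.frag_end
            else:
                assert row.strand == "+" and row.start == tr.frag_start
            checked += 1
        assert checked > 0.95 * len(asn)


class TestCountUmis:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)

    def test_pcr_duplicates_collapse(self):
        rows = [
            (f"r{i}", "S1", "AAAAAA", MAPPED, "G1", "G1.T1", "+", 100, 200)
            for i in range(3)
        ]
        mat = count_umis(self._frame(rows), policy="umi_pos")
        assert mat.total == 1

    def test_policy_contrast_same_umi_distant_starts(self):
        rows = [
            ("r1", "S1", "AAAAAA", MAPPED, "G1", "G1.T1", "+", 100, 200),
            ("r2", "S1", "AAAAAA", MAPPED, "G1", "G1.T1", "+", 400, 500),
        ]
        assert count_umis(self._frame(rows), policy="umi_pos").total == 2
        assert count_umis(self._frame(rows), policy="umi").total == 1

    def test_matrix_equals_ground_truth_with_unique_umis(
        self, errorfree_run, transcriptome
    ):
        """UMIs drawn without replacement per (sample, gene): deduplicated
        counts equal ground-truth fragment counts for every mapped read."""
        idx = build_kmer_index(transcriptome)
        asn = assign_reads(errorfree_run["records"], idx)
        mat = count_umis(asn, policy="umi_pos")
        mapped = asn[asn.status == MAPPED]
        truth_counts = (
            errorfree_run["truth"]
            .set_index("read_id")
            .loc[mapped.read_id]
            .groupby(["sample_id", "gene_id"])
            .size()
        )
        assert mat.total == len(mapped)
        for (sample, gene), n in truth_counts.items():
            gi = mat.gene_ids.index(gene)
            sj = mat.sample_ids.index(sample)
            assert mat.counts[gi, sj] == n

    def test_count_conservation(self, errorfree_run, transcriptome):
        idx = build_kmer_index(transcriptome)
        asn = assign_reads(errorfree_run["records"], idx)
        mat = count_umis(asn)
        assert mat.total <= errorfree_run["stats"].assigned_pairs


class TestSaturation:
    def test_full_fraction_reproduces_counts(self, errorfree_run, transcriptome):
        idx = build_kmer_index(transcriptome)
        asn = assign_reads(errorfree_run["records"][:2000], idx)
        table = downsample_saturation(asn, [1.0], seed=1)
        full = count_umis(asn)
        for _, row in table.iterrows():
            sj = full.sample_ids.index(row.sample_id)
            assert row.unique_umis == full.counts[:, sj].sum()

    def test_zero_fraction_rejected(self, errorfree_run, transcriptome):
        with pytest.raises(ValueError):
            downsample_saturation(pd.DataFrame(columns=ASSIGNMENT_COLUMNS), [0.0])

    def test_detection_monotone_in_depth(self, errorfree_run, transcriptome):
        idx = build_kmer_index(transcriptome)
        asn = assign_reads(errorfree_run["records"], idx)
        table = downsample_saturation(asn, np.arange(0.1, 1.01, 0.1), seed=2)
        for sample, grp in table.groupby("sample_id"):
            grp = grp.sort_values("fraction")
            assert (grp.genes_detected.diff().dropna() >= 0).all()
            assert (grp.unique_umis.diff().dropna() >= 0).all()


class TestMatrixIO:
    def test_mtx_round_trip_random_sparse(self, tmp_path):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 5, size=(200, 16)) * (rng.random((200, 16)) < 0.2)
        mat = ExpressionMatrix(
            counts.astype(np.int64),
            tuple(f"G{i}" for i in range(200)),
            tuple(f"S{j}" for j in range(16)),
        )
        write_matrix(mat, tmp_path / "m")
        loaded = read_matrix(tmp_path / "m")
        assert np.array_equal(loaded.counts, mat.counts)
        assert loaded.gene_ids == mat.gene_ids
        assert loaded.sample_ids == mat.sample_ids
        header = (tmp_path / "m" / "matrix.mtx").read_text().splitlines()[0]
        assert header.startswith("%%MatrixMarket matrix coordinate")

    def test_tsv_round_trip(self, tmp_path):
        mat = ExpressionMatrix(
            np.arange(12).reshape(4, 3), ("a", "b", "c", "d"), ("x", "y", "z")
        )
        write_matrix_tsv(mat, tmp_path / "m.tsv")
        loaded = read_matrix_tsv(tmp_path / "m.tsv")
        assert np.array_equal(loaded.counts, mat.counts)

    def test_label_mismatch_rejected(self, tmp_path):
        mat = ExpressionMatrix(np.ones((2, 2), dtype=int), ("a", "b"), ("x", "y"))
        write_matrix(mat, tmp_path / "m")
        (tmp_path / "m" / "genes.tsv").write_text("a\nb\nc\n")
        with pytest.raises(ValueError):
            read_matrix(tmp_path / "m")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(np.array([[-1]]), ("g",), ("s",))
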