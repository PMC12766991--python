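"""Gene-body coverage, bias index, barnyard calls and the QC report."""

import json

import numpy as np
import pandas as pd
import pytest

from cbtiseq.barcodes import SampleSheet
from cbtiseq.qc import (
    MIXED,
    CoverageProfile,
    barnyard_classify,
    coverage_bias_index,
    gene_body_coverage,
    qc_report,
    validate_qc_report,
    write_coverage_tsv,
)
from cbtiseq.quant import ExpressionMatrix
from cbtiseq.simulate import SimConfig, make_transcriptome, simulate_library


def truth_as_assignments(truth: pd.DataFrame) -> pd.DataFrame:
    return truth.rename(columns={"frag_start": "start", "frag_end": "end"})


def simulate_profile(set_a, set_b, delta, seed, reads_per_sample=8000):
    t = make_transcriptome(20, seed=60)
    sheet = SampleSheet.diagonal(2)
    cfg = SimConfig(reads_per_sample=reads_per_sample, degradation_bias=delta, seed=seed)
    _, truth = simulate_library(t, sheet, set_a, set_b, cfg)
    return gene_body_coverage(truth_as_assignments(truth), t), len(truth)


class TestCoverage:
    def test_flat_profile_at_delta_zero(self, set_a, set_b):
        """Uniform tagmentation: every percentile bin within 4 binomial SE
        of the flat expectation 0.01."""
        profile, n = simulate_profile(set_a, set_b, delta=0.0, seed=61)
        se = np.sqrt(0.01 * 0.99 / n)
        assert np.abs(profile.bins - 0.01).max() < 4 * se

    def test_bins_sum_to_one(self, set_a, set_b):
        profile, _ = simulate_profile(set_a, set_b, delta=1.0, seed=62, reads_per_sample=500)
        assert abs(profile.bins.sum() - 1.0) < 1e-9

    def test_single_read_covering_first_ten_bins(self):
        t = make_transcriptome(1, mean_length=1000, sd_length=0, seed=63)
        tid = t.records[0].transcript_id
        asn = pd.DataFrame({"transcript_id": [tid], "start": [0], "end": [100]})
        profile = gene_body_coverage(asn, t, min_len=500)
        assert np.allclose(profile.bins[:10], 0.1)
        assert np.allclose(profile.bins[10:], 0.0)

    def test_no_eligible_transcripts_errors(self):
        t = make_transcriptome(1, mean_length=1000, sd_length=0, seed=63)
        with pytest.raises(ValueError):
            gene_body_coverage(
                pd.DataFrame(columns=["transcript_id", "start", "end"]), t
            )


class TestBiasIndex:
    def test_flat_profile_gives_one(self):
        profile = CoverageProfile(np.full(100, 0.01), 1)
        assert coverage_bias_index(profile) == pytest.approx(1.0)

    def test_all_mass_in_last_bin_is_inf(self):
        bins = np.zeros(100)
        bins[99] = 1.0
        assert coverage_bias_index(CoverageProfile(bins, 1)) == float("inf")

    def test_linear_ramp_closed_form(self):
        """bins[i] = (i+1)/5050: 3' quintile mean / 5' quintile mean
        = mean(81..100) / mean(1..20) = 90.5 / 10.5."""
        bins = np.arange(1, 101) / 5050.0
        assert coverage_bias_index(CoverageProfile(bins, 1)) == pytest.approx(90.5 / 10.5)

    def test_strictly_increasing_in_degradation(self, set_a, set_b):
        """The 3'/5' bias index grows with the degradation parameter, at
        three seeds each."""
        for seed in (70, 71, 72):
            indices = [
                coverage_bias_index(
                    simulate_profile(set_a, set_b, delta, seed, reads_per_sample=3000)[0]
                )
                for delta in (0.0, 1.0, 2.0)
            ]
            assert indices[0] < indices[1] < indices[2]


def _species_matrix(counts_by_sample):
    genes = ("HUMAN_G1", "HUMAN_G2", "MOUSE_G1", "MOUSE_G2")
    samples = tuple(counts_by_sample)
    counts = np.array(
        [
            [counts_by_sample[s][0], counts_by_sample[s][1],
             counts_by_sample[s][2], counts_by_sample[s][3]]
            for s in samples
        ]
    ).T
    return ExpressionMatrix(counts, genes, samples)


class TestBarnyard:
    def test_minor_below_threshold_keeps_species(self):
        mat = _species_matrix({"S1": (60, 30, 5, 5)})
        (call,) = barnyard_classify(mat)
        assert call.call == "HUMAN" and call.minor_fraction == pytest.approx(0.10)

    def test_minor_above_threshold_mixed(self):
        mat = _species_matrix({"S1": (50, 25, 15, 10)})
        (call,) = barnyard_classify(mat)
        assert call.call == MIXED and call.minor_fraction == pytest.approx(0.25)

    def test_exactly_at_threshold_not_mixed(self):
        """The rule is strictly 'more than 20%': an 80/20 split keeps its
        major-species call."""
        mat = _species_matrix({"S1": (40, 40, 10, 10)})
        (call,) = barnyard_classify(mat)
        assert call.minor_fraction == pytest.approx(0.20)
        assert call.call == "HUMAN"

    def test_zero_count_sample_undetermined(self):
        mat = _species_matrix({"S1": (0, 0, 0, 0)})
        (call,) = barnyard_classify(mat)
        assert call.call == "UNDETERMINED"

    def test_label_permutation_swaps_calls_preserves_mixed(self):
        mat = _species_matrix({
            "S1": (90, 0, 10, 0), "S2": (5, 5, 60, 30), "S3": (50, 10, 30, 10)
        })
        forward = barnyard_classify(mat)
        swapped_species = {
            g: ("MOUSE" if g.startswith("HUMAN") else "HUMAN") for g in mat.gene_ids
        }
        backward = barnyard_classify(mat, species_of=swapped_species)
        for f, b in zip(forward, backward):
            if f.call == MIXED:
                assert b.call == MIXED
            elif f.call == "HUMAN":
                assert b.call == "MOUSE"
            elif f.call == "MOUSE":
                assert b.call == "HUMAN"

    def test_simulated_barnyard_pure_samples(self, set_a, set_b):
        """Samples expressing only one species' transcriptome are called
        cleanly; a sample mixing both is MIXED."""
        t = make_transcriptome(40, species_mix=(20, 20), seed=80)
        sheet = SampleSheet.diagonal(3)
        cfg = SimConfig(reads_per_sample=500, seed=81)
        _, truth = simulate_library(t, sheet, set_a, set_b, cfg)
        # emulate species-pure samples by filtering ground-truth fragments
        keep = (
            ((truth.sample_id == "S01") & truth.gene_id.str.startswith("HUMAN")) |
            ((truth.sample_id == "S02") & truth.gene_id.str.startswith("MOUSE")) |
            (truth.sample_id == "S03")
        )
        sub = truth[keep]
        counts = sub.groupby(["gene_id", "sample_id"]).size().unstack(fill_value=0)
        mat = ExpressionMatrix(
            counts.to_numpy(), tuple(counts.index), tuple(counts.columns)
        )
        calls = {c.sample_id: c.call for c in barnyard_classify(mat)}
        assert calls["S01"] == "HUMAN"
        assert calls["S02"] == "MOUSE"
        assert calls["S03"] == MIXED


class TestReport:
    def test_report_complete_and_round_trips(self, errorfree_run, transcriptome):
        from cbtiseq.quant import assign_reads, build_kmer_index, count_umis

        idx = build_kmer_index(transcriptome)
        asn = assign_reads(errorfree_run["records"][:1000], idx)
        mat = count_umis(asn)
        profile = gene_body_coverage(asn, transcriptome)
        report = qc_report(errorfree_run["stats"], mat, profile)
        validate_qc_report(report)
        assert json.loads(json.dumps(report)) == report
        # values agree with the constituent modules
        assert report["demux"]["assigned_pairs"] == errorfree_run["stats"].assigned_pairs
        assert report["expression"]["total_umis"] == mat.total
        assert report["coverage"]["bias_index"] == coverage_bias_index(profile)

    def test_missing_section_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            validate_qc_report({"demux": {}})

    def test_coverage_tsv(self, tmp_path):
        profile = CoverageProfile(np.full(100, 0.01), 2)
        write_coverage_tsv(profile, tmp_path / "cov.tsv")
        df = pd.read_csv(tmp_path / "cov.tsv", sep="\t")
        assert len(df) == 100 and df.mean_coverage.sum() == pytest.approx(1.0)
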