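"""ROH caller semantics, length classes and F_ROH summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohfst import (
    BreedSpec,
    SimConfig,
    classify_segments,
    compute_l_auto,
    detect_roh,
    expected_roh_length,
    simulate_dataset,
    summarize,
)
from rohfst.dataset import MISSING

from oracles import roh_oracle
from test_qc import dataset_from_calls


def single_sample_dataset(calls, positions, chrom="1"):
    calls = np.asarray(calls, dtype=np.int8).reshape(1, -1)
    return dataset_from_calls(calls, chroms=[chrom] * calls.shape[1], positions=positions)


def random_roh_string(rng, n):
    """Genotype string with long homozygous stretches and sparse breaks."""
    calls = rng.choice(
        np.array([0, 2, 1, MISSING], dtype=np.int8), size=n, p=[0.46, 0.46, 0.05, 0.03]
    )
    gaps = rng.choice([60_000, 120_000, 200_000, 700_000], size=n - 1,
                      p=[0.5, 0.3, 0.18, 0.02])
    positions = np.concatenate([[1], 1 + np.cumsum(gaps)])
    return calls, positions


class TestDetectRoh:
    def test_25_hom_snps_over_3mb_is_one_roh(self):
        positions = np.linspace(1_000_000, 4_000_000, 25).astype(np.int64)
        segments = detect_roh(single_sample_dataset([0] * 25, positions))
        assert len(segments) == 1
        seg = segments.iloc[0]
        assert seg["n_snps"] == 25
        assert seg["length_bp"] == 3_000_000
        assert seg["length_class"] == "2-4"

    def test_25_hom_snps_under_2mb_is_no_roh(self):
        positions = np.linspace(1_000_000, 2_500_000, 25).astype(np.int64)
        segments = detect_roh(single_sample_dataset([2] * 25, positions))
        assert len(segments) == 0

    def test_heterozygote_breaks_run(self):
        positions = np.linspace(1_000_000, 7_000_000, 50).astype(np.int64)
        calls = [0] * 25 + [1] + [0] * 24
        segments = detect_roh(single_sample_dataset(calls, positions))
        assert len(segments) == 2
        assert (segments["n_missing"] == 0).all()

    def test_oversized_gap_breaks_run(self):
        positions = np.concatenate(
            [np.arange(1, 26) * 100_000, 3_200_000 + np.arange(25) * 100_000]
        )
        segments = detect_roh(single_sample_dataset([0] * 50, positions))
        # gap of 700 kb between the halves; each half spans 2.4 Mb
        assert len(segments) == 2

    def test_scattered_missing_calls_match_exhaustive_oracle(self):
        positions = (1 + np.arange(60)) * 100_000
        calls = np.zeros(60, dtype=np.int8)
        calls[[10, 30, 50]] = MISSING
        segments = detect_roh(single_sample_dataset(calls, positions))
        expected = roh_oracle(calls, positions)
        got = [
            (int(np.flatnonzero(positions == s)[0]), int(np.flatnonzero(positions == e)[0]))
            for s, e in zip(segments["start_bp"], segments["end_bp"])
        ]
        assert got == expected
        assert (segments["n_missing"] <= 2).all()

    def test_missing_calls_never_terminal(self, rng):
        for case in range(50):
            calls, positions = random_roh_string(rng, 150)
            segments = detect_roh(single_sample_dataset(calls, positions))
            for _, seg in segments.iterrows():
                i = int(np.flatnonzero(positions == seg["start_bp"])[0])
                j = int(np.flatnonzero(positions == seg["end_bp"])[0])
                assert calls[i] in (0, 2) and calls[j] in (0, 2)

    def test_matches_exhaustive_oracle_on_random_strings(self, rng):
        for case in range(200):
            n = int(rng.integers(20, 200))
            calls, positions = random_roh_string(rng, n)
            segments = detect_roh(single_sample_dataset(calls, positions))
            expected = roh_oracle(calls, positions)
            got = [
                (
                    int(np.flatnonzero(positions == s)[0]),
                    int(np.flatnonzero(positions == e)[0]),
                )
                for s, e in zip(segments["start_bp"], segments["end_bp"])
            ]
            assert got == expected, f"case {case}"

    def test_raising_min_thresholds_never_increases_count(self, rng):
        for _ in range(30):
            calls, positions = random_roh_string(rng, 180)
            ds = single_sample_dataset(calls, positions)
            base = len(detect_roh(ds))
            assert len(detect_roh(ds, min_snps=30)) <= base
            assert len(detect_roh(ds, min_length_bp=4_000_000)) <= base

    def test_raising_missing_budget_never_decreases_coverage(self, rng):
        for _ in range(30):
            calls, positions = random_roh_string(rng, 180)
            ds = single_sample_dataset(calls, positions)
            cov0 = detect_roh(ds, max_missing=0)["length_bp"].sum()
            cov2 = detect_roh(ds, max_missing=2)["length_bp"].sum()
            cov6 = detect_roh(ds, max_missing=6)["length_bp"].sum()
            assert cov0 <= cov2 <= cov6

    def test_negative_threshold_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            detect_roh(small_dataset, max_missing=-1)


class TestLengthClasses:
    @pytest.mark.parametrize(
        "length_bp,label",
        [
            (3_999_999, "2-4"),
            (4_000_000, "4-8"),
            (7_999_999, "4-8"),
            (8_000_000, "8-16"),
            (17_000_000, ">16"),
        ],
    )
    def test_half_open_bin_edges(self, length_bp, label):
        seg = pd.DataFrame(
            [{"sample_id": "s", "chromosome": "1", "start_bp": 1,
              "end_bp": 1 + length_bp, "length_bp": length_bp,
              "n_snps": 30, "n_missing": 0}]
        )
        assert classify_segments(seg)["length_class"].iloc[0] == label

    def test_segment_below_minimum_rejected(self):
        seg = pd.DataFrame(
            [{"sample_id": "s", "chromosome": "1", "start_bp": 1,
              "end_bp": 1_500_001, "length_bp": 1_500_000,
              "n_snps": 30, "n_missing": 0}]
        )
        with pytest.raises(ValueError):
            classify_segments(seg)


class TestSummaries:
    def test_individual_without_segments_counts_in_n_zero(self):
        positions = np.linspace(1_000_000, 4_000_000, 25).astype(np.int64)
        calls = np.vstack([[0] * 25, [1] * 25]).astype(np.int8)
        ds = dataset_from_calls(calls, positions=positions)
        segments = detect_roh(ds)
        summary = summarize(segments, ds)
        ind = summary.per_individual.set_index("sample_id")
        assert ind.loc["s1", "froh_total"] == 0
        assert summary.per_breed.iloc[0]["n_zero"] == 1

    def test_froh_arithmetic_with_published_denominator(self):
        seg = pd.DataFrame(
            [{"sample_id": "s0", "chromosome": "1", "start_bp": 1,
              "end_bp": 24_630_001, "length_bp": 24_630_000,
              "n_snps": 400, "n_missing": 0}]
        )
        positions = np.linspace(1_000_000, 30_000_000, 25).astype(np.int64)
        ds = dataset_from_calls(np.zeros((1, 25), dtype=np.int8), positions=positions)
        summary = summarize(classify_segments(seg), ds, l_auto_bp=2_463_000_000)
        assert summary.per_individual["froh_total"].iloc[0] == pytest.approx(0.01)

    def test_class_froh_sums_to_total(self, rng):
        cfg = SimConfig(
            seed=17,
            breeds=[BreedSpec("A", 8, drift_c=0.05, autozygous_fraction=0.2, generations=5)],
            chromosome_lengths_bp={"1": 60_000_000, "2": 60_000_000},
            markers_per_chromosome=1500,
        )
        ds, _ = simulate_dataset(cfg)
        summary = summarize(detect_roh(ds), ds)
        ind = summary.per_individual
        total = sum(ind[f"froh_{c}"] for c in ("2-4", "4-8", "8-16", ">16"))
        np.testing.assert_allclose(total, ind["froh_total"], atol=1e-12)
        assert ((ind["froh_total"] >= 0) & (ind["froh_total"] <= 1)).all()

    def test_n_zero_accounting(self, rng):
        cfg = SimConfig(
            seed=3,
            breeds=[BreedSpec("A", 10, drift_c=0.05, autozygous_fraction=0.05, generations=10)],
            chromosome_lengths_bp={"1": 60_000_000},
            markers_per_chromosome=1200,
        )
        ds, _ = simulate_dataset(cfg)
        summary = summarize(detect_roh(ds), ds)
        row = summary.per_breed.iloc[0]
        with_roh = (summary.per_individual["n_roh"] > 0).sum()
        assert row["n_zero"] + with_roh == row["n"]

    def test_l_auto_is_marker_span(self, small_dataset):
        spans = small_dataset.markers.groupby("chromosome")["position_bp"].agg(["min", "max"])
        assert compute_l_auto(small_dataset) == int((spans["max"] - spans["min"]).sum())

    def test_recent_vs_ancient_inbreeding_length_classes(self):
        """Recent autozygosity (g=3) is dominated by >16 Mb runs; older
        autozygosity (g=25) by 2-4 Mb runs."""
        coverage = {}
        for g in (3, 25):
            cfg = SimConfig(
                seed=29,
                breeds=[BreedSpec("A", 12, drift_c=0.05,
                                  autozygous_fraction=0.2, generations=g)],
                chromosome_lengths_bp={"1": 80_000_000, "2": 80_000_000},
                markers_per_chromosome=2500,
            )
            ds, _ = simulate_dataset(cfg)
            summary = summarize(detect_roh(ds), ds)
            row = summary.per_breed.iloc[0]
            coverage[g] = {c: row[f"froh_{c}"] for c in ("2-4", "4-8", "8-16", ">16")}
        assert max(coverage[3], key=coverage[3].get) == ">16"
        assert max(coverage[25], key=coverage[25].get) == "2-4"


class TestExpectedRohLength:
    @pytest.mark.parametrize("g,mb", [(25, 2.0), (50, 1.0), (1, 50.0), (3, 100 / 6)])
    def test_inverse_exponential_mean(self, g, mb):
        assert expected_roh_length(g) == pytest.approx(mb)

    def test_nonpositive_generations_rejected(self):
        with pytest.raises(ValueError):
            expected_roh_length(0)
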