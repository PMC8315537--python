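"""Marker container, CSV round trips and per-marker QC statistics."""

import numpy as np
import pandas as pd
import pytest

from dartpop import (
    MarkerMatrix,
    call_rate,
    classify_snp_type,
    compute_qc,
    filter_markers,
    pic,
    read_marker_csv,
    reproducibility,
    summarize_pic_bins,
    tstv_table,
    write_marker_csv,
)
from dartpop.markers import MISSING, MarkerFormatError


def _mk(scores, platform="snp", **kw):
    scores = np.asarray(scores, dtype=np.int8)
    kw.setdefault("marker_ids", [f"m{i}" for i in range(scores.shape[0])])
    kw.setdefault("sample_ids", [f"s{j}" for j in range(scores.shape[1])])
    return MarkerMatrix(platform=platform, scores=scores, **kw)


class TestContainer:
    def test_rejects_illegal_scores(self):
        with pytest.raises(MarkerFormatError, match="illegal score"):
            _mk([[0, 3]], platform="silico")

    def test_rejects_duplicate_ids(self):
        with pytest.raises(MarkerFormatError, match="duplicate marker"):
            _mk([[0], [1]], marker_ids=["m", "m"])

    def test_replicate_pairs_must_reference_samples(self):
        with pytest.raises(MarkerFormatError, match="unknown sample"):
            _mk([[0, 1]], replicate_pairs=[("s0", "nope")])


class TestCsvIO:
    def test_round_trip(self, tmp_path, small_collection):
        _, snp, sil, _ = small_collection
        for m in (snp, sil):
            p = tmp_path / f"{m.platform}.csv"
            write_marker_csv(m, p)
            back = read_marker_csv(p, m.platform)
            assert back.marker_ids == m.marker_ids
            assert back.sample_ids == m.sample_ids
            assert np.array_equal(back.scores, m.scores)
            assert sorted(back.replicate_pairs) == sorted(m.replicate_pairs)

    def test_illegal_token_names_cell(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("MarkerID,sampA,sampB\nm1,0,1\nm2,3,0\n")
        with pytest.raises(MarkerFormatError, match=r"m2.*sampA"):
            read_marker_csv(p, "silico")

    def test_dart_coding_harmonized_to_dosage(self, tmp_path):
        p = tmp_path / "dart.csv"
        # DArT convention: 1 = alternate homozygote, 2 = heterozygote
        p.write_text("MarkerID,a,b\nm1,1,2\nm2,0,1\n")
        m = read_marker_csv(p, "snp", snp_coding="dart")
        assert m.scores.tolist() == [[2, 1], [0, 2]]


class TestCallRate:
    @pytest.mark.parametrize(
        "row,expected",
        [([0, 1, 2], 1.0), ([0, MISSING, 2], 2 / 3), ([MISSING, MISSING, MISSING], 0.0)],
    )
    def test_examples(self, row, expected):
        assert call_rate(_mk([row])) == pytest.approx(expected)

    def test_87_samples_3_missing(self):
        row = [1] * 84 + [MISSING] * 3
        assert call_rate(_mk([row])) == pytest.approx(84 / 87)

    def test_invariant_to_sample_order(self, rng):
        m = _mk(rng.integers(-1, 3, size=(30, 10)))
        perm = rng.permutation(10)
        m2 = m.select_samples([m.sample_ids[j] for j in perm])
        assert np.allclose(call_rate(m), call_rate(m2))


class TestReproducibility:
    def _with_pairs(self, cols):
        scores = np.asarray(cols, dtype=np.int8).T  # one marker per row? build markers x samples
        return scores

    def test_concordant_pairs(self):
        m = _mk(
            [[0, 0, 1, 1, 2, 2]],
            replicate_pairs=[("s0", "s1"), ("s2", "s3"), ("s4", "s5")],
        )
        vals, flags = reproducibility(m)
        assert vals[0] == 1.0 and not flags[0]

    def test_partial_concordance(self):
        # pairs (0,0), (1,2), (2,2) -> 2/3
        m = _mk([[0, 0, 1, 2, 2, 2]], replicate_pairs=[("s0", "s1"), ("s2", "s3"), ("s4", "s5")])
        vals, _ = reproducibility(m)
        assert vals[0] == pytest.approx(2 / 3)

    def test_no_scorable_pair_convention(self):
        m = _mk([[1, MISSING]], replicate_pairs=[("s0", "s1")])
        vals, flags = reproducibility(m)
        assert vals[0] == 1.0 and flags[0]

    def test_empty_registry_is_an_error(self):
        with pytest.raises(ValueError, match="replicate registry"):
            reproducibility(_mk([[0, 1]]))


class TestPic:
    def test_symmetric_snp_is_half(self):
        row = [0] * 25 + [1] * 50 + [2] * 25
        assert pic(_mk([row])) == pytest.approx(0.5)

    def test_snp_closed_form_p09(self):
        # p = 0.9 -> 1 - 0.81 - 0.01 = 0.18
        row = [2] * 81 + [1] * 18 + [0] * 1
        assert pic(_mk([row])) == pytest.approx(0.18)

    def test_monomorphic_silico_is_zero(self):
        assert pic(_mk([[1, 1, 1]], platform="silico")) == pytest.approx(0.0)

    def test_allele_relabel_invariance(self, rng):
        g = rng.integers(0, 3, size=(50, 40))
        assert np.allclose(pic(_mk(g)), pic(_mk(2 - g)))

    def test_bounded_by_half(self, rng):
        g = rng.integers(-1, 3, size=(200, 30))
        g[0] = MISSING  # all-missing marker -> nan, excluded
        vals = pic(_mk(g))
        ok = ~np.isnan(vals)
        assert ((vals[ok] >= 0) & (vals[ok] <= 0.5 + 1e-12)).all()


class TestSnpType:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            ("A>G", "transition"),
            ("G>A", "transition"),
            ("C>T", "transition"),
            ("G>C", "transversion"),
            ("A>T", "transversion"),
            ("a/c", "transversion"),
        ],
    )
    def test_classes(self, pair, expected):
        assert classify_snp_type(pair) == expected

    @pytest.mark.parametrize("bad", ["A>A", "A>N", "ACG", ""])
    def test_rejects_non_snps(self, bad):
        with pytest.raises(ValueError):
            classify_snp_type(bad)


class TestFilter:
    def test_threshold_counts(self):
        m = _mk(np.ones((5, 4), dtype=np.int8))
        qc = compute_qc(m)
        qc.call_rate = np.array([1.0, 0.96, 0.94, 1.0, 0.90])
        filt, report = filter_markers(m, qc, min_call_rate=0.95)
        assert report["n_retained"] == 3
        assert filt.marker_ids == ["m0", "m1", "m3"]

    def test_zero_thresholds_keep_all(self, small_collection):
        _, snp, _, _ = small_collection
        qc = compute_qc(snp)
        filt, report = filter_markers(snp, qc, 0.0, 0.0)
        assert report["n_retained"] == snp.n_markers

    def test_idempotent(self, small_collection):
        _, snp, _, _ = small_collection
        once, _ = filter_markers(snp, compute_qc(snp))
        twice, rep2 = filter_markers(once, compute_qc(once))
        assert twice.marker_ids == once.marker_ids
        assert rep2["n_removed"] == 0

    def test_empty_result_allowed(self):
        m = _mk(np.full((3, 4), MISSING, dtype=np.int8))
        qc = compute_qc(m)
        filt, report = filter_markers(m, qc)
        assert report["n_retained"] == 0 and filt.n_markers == 0

    def test_threshold_out_of_range(self, small_collection):
        _, snp, _, _ = small_collection
        with pytest.raises(ValueError):
            filter_markers(snp, compute_qc(snp), min_call_rate=1.5)

    def test_precomputed_reproducibility_preferred(self):
        # provider-QC column says perfect even though the in-data pair disagrees
        m = _mk(
            [[0, 1]],
            replicate_pairs=[("s0", "s1")],
            precomputed={"reproducibility": np.array([1.0])},
        )
        qc = compute_qc(m)
        assert qc.reproducibility[0] == 1.0
        qc2 = compute_qc(m, prefer_precomputed=False)
        assert qc2.reproducibility[0] == 0.0


class TestPicBins:
    def test_binning(self):
        df = summarize_pic_bins([0.05, 0.45, 0.45, 0.45])
        assert df["percent"].tolist() == [25.0, 0.0, 0.0, 0.0, 75.0]

    def test_single_bin(self):
        df = summarize_pic_bins([0.25] * 7)
        assert df["percent"].tolist() == [0.0, 0.0, 100.0, 0.0, 0.0]

    def test_boundary_05_in_last_bin(self):
        assert summarize_pic_bins([0.5])["count"].tolist() == [0, 0, 0, 0, 1]

    def test_empty_input_all_zero(self):
        df = summarize_pic_bins([])
        assert df["count"].sum() == 0

    def test_percentages_sum_to_100(self, rng):
        df = summarize_pic_bins(rng.uniform(0, 0.5, size=500))
        assert df["percent"].sum() == pytest.approx(100.0)


class TestTsTv:
    def test_single_marker(self):
        m = _mk([[0, 1]], allele_pair=["C>T"])
        df = tstv_table(m).set_index("class")
        assert df.loc["total_transition", "count"] == 1
        assert df.loc["total_transition", "frequency"] == pytest.approx(1.0)
        assert df.loc["total_transversion", "count"] == 0

    def test_fractions_sum_to_one(self, small_collection):
        _, snp, _, _ = small_collection
        df = tstv_table(snp).set_index("class")
        total = df.loc["total_transition", "frequency"] + df.loc["total_transversion", "frequency"]
        assert total == pytest.approx(1.0)

    def test_unparseable_pairs_counted_na(self):
        m = _mk([[0], [1], [2]], allele_pair=["A>G", "??", "G>T"])
        df = tstv_table(m).set_index("class")
        assert df.loc["NA", "count"] == 1
        # NA excluded from denominators
        assert df.loc["A/G", "frequency"] == pytest.approx(0.5)
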