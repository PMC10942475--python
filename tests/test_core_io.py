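import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifdiff import core_io
from motifdiff.core_io import (
    FragmentParseError,
    FragmentSet,
    MotifMatchMatrix,
    classify_fragments,
    count_overlaps,
    merge_intervals,
    read_fragments,
    read_ppm,
    resize_and_merge_peaks,
    tn5_insertions,
    write_fragments,
)

from conftest import make_fragments


class TestReadFragments:
    def test_three_column_parse(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("chr1\t100\t200\nchr1\t150\t260\n")
        fs = read_fragments(p)
        assert len(fs) == 2
        assert list(fs.lengths) == [100, 110]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("")
        fs = read_fragments(p)
        assert len(fs) == 0

    def test_inverted_record_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("chr1\t200\t100\nchr1\t10\t20\n")
        fs = read_fragments(p)
        assert len(fs) == 1
        assert fs.n_rejected == 1

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("chr1\t100\t200\nchr1\tabc\t300\n")
        with pytest.raises(FragmentParseError) as err:
            read_fragments(p)
        assert err.value.line == 2

    def test_duplicate_counts_as_weights_or_expanded(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("chr1\t100\t200\tsampleX\t3\n")
        fs = read_fragments(p)
        assert len(fs) == 1 and fs.total_weight == 3
        fs2 = read_fragments(p, expand_duplicates=True)
        assert len(fs2) == 3 and fs2.total_weight == 3

    def test_sample_column_filter(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("chr1\t1\t50\ts1\nchr1\t5\t60\ts2\n")
        assert len(read_fragments(p, sample_id="s1")) == 1

    def test_round_trip(self, tmp_path):
        fs = make_fragments([("chr1", 0, 80), ("chr2", 5, 505, 2)], sample_id="sA")
        p = tmp_path / "out.tsv"
        write_fragments(fs, p)
        back = read_fragments(p, sample_id="sA")
        pd.testing.assert_frame_equal(
            back.df[["chrom", "start", "end", "weight"]],
            fs.df[["chrom", "start", "end", "weight"]],
        )


class TestResizeAndMerge:
    def test_overlapping_inputs_merge_then_resize(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [250]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [400]})
        out = resize_and_merge_peaks([a, b], width=300)
        assert out.iloc[0].tolist() == ["chr1", 100, 400]

    def test_identity_width(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [300]})
        out = resize_and_merge_peaks([a], width=300)
        assert out.iloc[0].tolist() == ["chr1", 0, 300]

    def test_disjoint_peaks_with_edge_clipping(self):
        a = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 500], "end": [100, 600]})
        out = resize_and_merge_peaks([a], width=150)
        # [0,100): mid 50 -> [-25,125) truncated at 0 -> [0,125)
        assert out.iloc[0][["start", "end"]].tolist() == [0, 125]
        assert out.iloc[1][["start", "end"]].tolist() == [475, 625]

    def test_empty_input_list_errors(self):
        with pytest.raises(ValueError):
            resize_and_merge_peaks([], width=300)

    @given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 400)),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_midpoints_preserved_away_from_edges(self, intervals):
        df = pd.DataFrame(
            {"chrom": "chr1", "start": [s for s, w in intervals],
             "end": [s + w for s, w in intervals]}
        )
        merged = merge_intervals(df)
        out = resize_and_merge_peaks([df], width=200)
        mids_in = (merged["start"] + merged["end"]) / 2
        inner = out["start"] > 0
        mids_out = (out["start"] + out["end"]) / 2
        assert (np.abs(mids_in[inner] - mids_out[inner]) <= 1).all()


class TestCountOverlaps:
    peaks = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [100, 300], "end": [200, 400]})

    def test_single_overlap(self):
        fs = make_fragments([("chr1", 150, 160)])
        assert count_overlaps([fs], self.peaks)[:, 0].tolist() == [1, 0]

    def test_spanning_fragment_counts_both(self):
        fs = make_fragments([("chr1", 190, 310)])
        assert count_overlaps([fs], self.peaks)[:, 0].tolist() == [1, 1]

    def test_no_fragments_zero_matrix(self):
        fs = make_fragments([("chr9", 1, 2)])  # wrong chromosome
        out = count_overlaps([fs], self.peaks)
        assert out.shape == (2, 1) and out.sum() == 0

    def test_weights_summed(self):
        fs = make_fragments([("chr1", 150, 160, 4)])
        assert count_overlaps([fs], self.peaks)[0, 0] == 4

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_pk, n_fr = 40, 200
        ps = rng.integers(0, 3000, n_pk)
        peaks = pd.DataFrame(
            {"chrom": rng.choice(["c1", "c2"], n_pk), "start": ps,
             "end": ps + rng.integers(1, 300, n_pk)}
        )
        fsr = rng.integers(0, 3000, n_fr)
        fs = make_fragments(
            list(zip(rng.choice(["c1", "c2"], n_fr), fsr,
                     fsr + rng.integers(1, 500, n_fr)))
        )
        fast = count_overlaps([fs], peaks)[:, 0]
        slow = np.zeros(n_pk, dtype=int)
        for _, fr in fs.df.iterrows():
            for i, pk in peaks.iterrows():
                if fr.chrom == pk.chrom and fr.start < pk.end and fr.end > pk.start:
                    slow[i] += 1
        assert fast.tolist() == slow.tolist()


class TestClassifyFragments:
    def test_length_class_thresholds(self):
        fs = make_fragments(
            [("c", 0, L) for L in (120, 121, 300, 301, 500, 501)]
        )
        assert classify_fragments(fs).tolist() == [
            "NF", "mono", "mono", "di", "di", "multi"
        ]

    def test_nucleosome_free_bounds(self):
        fs = make_fragments([("c", 0, L) for L in (29, 30, 120, 121)])
        kept = classify_fragments(fs, "nucleosome_free")
        assert sorted(kept.lengths) == [30, 120]

    def test_empty_set(self):
        fs = make_fragments([("c", 0, 10)])
        fs.df = fs.df.iloc[:0]
        assert len(classify_fragments(fs)) == 0

    @given(st.lists(st.integers(1, 2000), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_partition(self, lengths):
        fs = make_fragments([("c", 0, L) for L in lengths])
        labels = classify_fragments(fs)
        assert len(labels) == len(lengths)
        assert set(labels) <= {"NF", "mono", "di", "multi"}


class TestTn5Insertions:
    def test_endpoints_no_shift(self):
        ins = tn5_insertions(make_fragments([("c", 100, 200)]))
        assert sorted(ins["pos"]) == [100, 199]

    def test_shifted(self):
        ins = tn5_insertions(make_fragments([("c", 100, 200)]), 4, 5)
        assert sorted(ins["pos"]) == [104, 194]

    def test_multiplicity(self):
        ins = tn5_insertions(make_fragments([("c", 10, 20), ("c", 10, 20)]))
        counts = ins.groupby("pos")["weight"].sum()
        assert counts[10] == 2 and counts[19] == 2

    def test_negative_positions_dropped(self):
        ins = tn5_insertions(make_fragments([("c", 2, 50)]), shift_plus=-5)
        assert sorted(ins["pos"]) == [49]


class TestMotifMatchMatrix:
    def test_score_where_no_indicator_rejected(self):
        with pytest.raises(ValueError):
            MotifMatchMatrix(np.array([[0]]), np.array([[2.0]]), ["m"])

    def test_scale_scores(self):
        mm = MotifMatchMatrix(
            np.array([[1, 1], [1, 0]]), np.array([[4.0, 3.0], [8.0, 0.0]]), ["a", "b"]
        )
        scaled = mm.scale_scores()
        assert scaled.score.max() == 1.0
        assert scaled.score[0, 0] == 0.5

    def test_mtx_round_trip(self, tmp_path):
        mm = MotifMatchMatrix(
            np.array([[1, 0], [1, 1]]), np.array([[4.0, 0.0], [1.0, 2.0]]), ["a", "b"]
        )
        core_io.write_matches_mtx(mm, tmp_path / "m")
        back = core_io.read_matches_mtx(tmp_path / "m")
        assert back.motif_ids == ["a", "b"]
        assert np.allclose(back.score, mm.score)
        assert (back.indicator == mm.indicator).all()


JASPAR_TEXT = """>M1 M1
A  [ 8 0 2 ]
C  [ 0 8 2 ]
G  [ 0 0 2 ]
T  [ 0 0 2 ]
>M2 M2
A  [ 0 4 ]
C  [ 0 4 ]
G  [ 8 0 ]
T  [ 0 0 ]
"""


class TestReadPPM:
    def test_jaspar_counts_normalized(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(JASPAR_TEXT)
        ppms = read_ppm(p, "jaspar")
        assert len(ppms) == 2
        assert np.allclose(ppms[0].matrix[:, 0], [1, 0, 0, 0])
        assert np.allclose(ppms[0].matrix.sum(axis=0), 1.0)

    def test_zero_count_column_uniform(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">Z Z\nA [ 0 8 ]\nC [ 0 0 ]\nG [ 0 0 ]\nT [ 0 0 ]\n")
        with pytest.warns(UserWarning):
            ppms = read_ppm(p, "jaspar")
        assert np.allclose(ppms[0].matrix[:, 0], 0.25)

    def test_meme_minimal_round(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF TEST\nletter-probability matrix: alength= 4 w= 2\n"
            " 0.25 0.25 0.25 0.25\n 1.0 0.0 0.0 0.0\n"
        )
        ppms = read_ppm(p, "meme")
        assert ppms[0].length == 2
        assert np.isclose(ppms[0].matrix[0, 1], 1.0)

    def test_write_read_round_trip(self, tmp_path):
        from motifdiff.core_io import MotifPPM, write_jaspar

        ppm = MotifPPM("X", np.array([[0.5, 0.1], [0.2, 0.3], [0.2, 0.4], [0.1, 0.2]]))
        path = tmp_path / "x.jaspar"
        write_jaspar([ppm], path)
        back = read_ppm(path, "jaspar")
        assert np.allclose(back[0].matrix, ppm.matrix, atol=1e-3)
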