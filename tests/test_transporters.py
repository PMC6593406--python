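import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from abscreen.transporters import (DEMO_UPTAKE_FAMILIES, FamilyCountMatrix,
                                   bray_curtis_matrix, build_family_matrix,
                                   filter_transporter_hits, nmds_ordinate,
                                   parse_tc_id, predict_tm_segments,
                                   tc_family)

SHORTLIST = set(DEMO_UPTAKE_FAMILIES)


def hit_row(q, s, pident=50.0, send=100, sstart=1, evalue=1e-10, bits=100.0):
    return (q, s, pident, send - sstart + 1, 0, 0, 1, 100, sstart, send,
            evalue, bits)


def hits_frame(rows):
    from abscreen.search import M8_COLUMNS
    return pd.DataFrame(rows, columns=M8_COLUMNS)


LENGTHS = {"tc|3.A.1.1.2": 100, "tc|2.A.56.1.1": 100, "tc|9.B.99.1.1": 100}


class TestTcIds:
    def test_tc_id_extracted_from_subject(self):
        assert parse_tc_id("P0AAG8|3.A.1.1.2") == "3.A.1.1.2"
        assert parse_tc_id("no_tc_here") is None

    def test_family_and_subfamily_truncation(self):
        assert tc_family("3.A.1.1.2", "family") == "3.A.1"
        assert tc_family("3.A.1.1.2", "subfamily") == "3.A.1.1"


class TestFilterTransporterHits:
    def test_passing_hit_in_shortlisted_family_is_kept(self):
        df = filter_transporter_hits(
            hits_frame([hit_row("orf1", "tc|3.A.1.1.2", pident=35.0,
                                send=80, evalue=1e-6)]),
            LENGTHS, SHORTLIST)
        assert list(df["qseqid"]) == ["orf1"]
        assert list(df["family"]) == ["3.A.1"]

    @pytest.mark.parametrize("kwargs", [
        {"pident": 29.0},                      # identity not > 30
        {"send": 70},                          # coverage not > 70
        {"evalue": 1e-4},                      # E not < 1e-5
    ])
    def test_threshold_failures_are_dropped(self, kwargs):
        df = filter_transporter_hits(
            hits_frame([hit_row("orf1", "tc|3.A.1.1.2", **kwargs)]),
            LENGTHS, SHORTLIST)
        assert df.empty

    def test_family_outside_shortlist_is_dropped(self):
        df = filter_transporter_hits(
            hits_frame([hit_row("orf1", "tc|9.B.99.1.1")]),
            LENGTHS, SHORTLIST)
        assert df.empty

    def test_best_bitscore_per_query_wins(self):
        rows = [hit_row("orf1", "tc|3.A.1.1.2", bits=80.0),
                hit_row("orf1", "tc|2.A.56.1.1", bits=120.0)]
        df = filter_transporter_hits(hits_frame(rows), LENGTHS, SHORTLIST)
        assert list(df["family"]) == ["2.A.56"]

    def test_unresolvable_tc_id_dropped_with_warning(self):
        rows = [hit_row("orf1", "junk_subject")]
        with pytest.warns(UserWarning, match="unresolvable"):
            df = filter_transporter_hits(hits_frame(rows),
                                         {"junk_subject": 100}, SHORTLIST)
        assert df.empty


class TestTmSegments:
    def test_poly_leucine_has_a_segment(self):
        assert len(predict_tm_segments("L" * 30)) >= 1

    def test_poly_aspartate_has_none(self):
        assert predict_tm_segments("D" * 30) == []

    def test_shorter_than_window_has_none(self):
        assert predict_tm_segments("L" * 10) == []

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            predict_tm_segments("")


class TestFamilyMatrix:
    def test_counts_and_tm_restriction(self):
        hits = {"g1": filter_transporter_hits(
            hits_frame([hit_row(f"orf{i}", "tc|3.A.1.1.2") for i in range(3)]),
            LENGTHS, SHORTLIST)}
        m = build_family_matrix(hits, {"g1": {"orf0", "orf1"}})
        assert m.counts_total.loc["g1", "3.A.1"] == 3
        assert m.counts_tm.loc["g1", "3.A.1"] == 2

    def test_no_hits_give_zero_matrix_with_declared_columns(self):
        empty = pd.DataFrame(columns=["qseqid", "family"])
        m = build_family_matrix({"g1": empty, "g2": empty}, {},
                                families=sorted(SHORTLIST))
        assert (m.counts_total.values == 0).all()
        assert list(m.counts_total.columns) == sorted(SHORTLIST)

    def test_column_sums_equal_total_kept_hits(self):
        rng = np.random.default_rng(0)
        hits = {}
        total_rows = 0
        for g in ("g1", "g2", "g3"):
            n = int(rng.integers(1, 6))
            rows = [hit_row(f"{g}_orf{i}",
                            rng.choice(["tc|3.A.1.1.2", "tc|2.A.56.1.1"]))
                    for i in range(n)]
            hits[g] = filter_transporter_hits(hits_frame(rows), LENGTHS,
                                              SHORTLIST)
            total_rows += len(hits[g])
        m = build_family_matrix(hits, {})
        assert m.counts_total.values.sum() == total_rows

    def test_tm_exceeding_total_is_rejected(self):
        total = pd.DataFrame([[1]], index=["g"], columns=["f"])
        tm = pd.DataFrame([[2]], index=["g"], columns=["f"])
        with pytest.raises(ValueError):
            FamilyCountMatrix(total, tm, {})


class TestBrayCurtis:
    @pytest.mark.parametrize("u, v, expected", [
        ([1, 1], [1, 1], 0.0),
        ([2, 0], [0, 2], 1.0),
        ([1, 0], [1, 1], 1 / 3),
    ])
    def test_closed_form_examples(self, u, v, expected):
        d = bray_curtis_matrix(np.array([u, v], dtype=float))
        assert d[0, 1] == pytest.approx(expected)

    def test_all_zero_rows_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            d = bray_curtis_matrix(np.zeros((2, 3)))
        assert d[0, 1] == 0.0

    @given(st.lists(st.lists(st.integers(0, 50), min_size=4, max_size=4),
                    min_size=2, max_size=6))
    def test_matches_scipy_and_satisfies_metric_axioms(self, rows):
        counts = np.array(rows, dtype=float)
        d = bray_curtis_matrix(counts)
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                if counts[i].sum() + counts[j].sum() > 0:
                    assert d[i, j] == pytest.approx(
                        scipy_braycurtis(counts[i], counts[j]))


class TestNmds:
    def planar_distances(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        return np.linalg.norm(pts[:, None] - pts[None], axis=2)

    def test_planar_realizable_distances_reach_near_zero_stress(self):
        res = nmds_ordinate(self.planar_distances(), restarts=20, seed=1)
        assert res.stress < 1e-3

    def test_same_seed_reproduces_coordinates_exactly(self):
        a = nmds_ordinate(self.planar_distances(), restarts=10, seed=7)
        b = nmds_ordinate(self.planar_distances(), restarts=10, seed=7)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_coordinates_are_centered(self):
        res = nmds_ordinate(self.planar_distances(), restarts=5, seed=0)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-12)

    def test_stress_non_increasing_in_restarts(self):
        counts = np.array([[5, 1, 0], [4, 2, 1], [0, 4, 4], [2, 2, 2.]])
        d = bray_curtis_matrix(counts)
        stresses = [nmds_ordinate(d, restarts=k, seed=3).stress
                    for k in (1, 5, 20)]
        assert stresses[0] >= stresses[1] >= stresses[2]

    def test_duplicated_genomes_stay_together(self):
        counts = np.array([[5, 1, 0], [5, 1, 0], [0, 4, 4], [2, 2, 2.]])
        res = nmds_ordinate(bray_curtis_matrix(counts), restarts=50, seed=3)
        sep = np.linalg.norm(res.coordinates[0] - res.coordinates[1])
        span = np.max(np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None], axis=2))
        assert sep < 0.01 * span

    def test_asymmetric_input_is_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            nmds_ordinate(np.array([[0.0, 1.0], [2.0, 0.0]]), restarts=1)
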