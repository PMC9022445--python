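import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamkit import ingest
from pamkit.ingest import (CountMatrix, Recording, Site, ValidationError,
                           apply_exclusions, dominance_share,
                           pairwise_distances, read_annotations,
                           read_selection_table, repeatability, retained,
                           summarize_species, write_annotations,
                           write_selection_table)
from pamkit.simulate import CommunitySpec, simulate_counts


class TestReadAnnotations:
    def test_long_to_wide_with_zero_fill(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text(
            "recording_id,site_id,date,species,count\n"
            "r1,s1,2018-06-01,AAA,3\n"
            "r2,s1,2018-06-02,BBB,7\n"
        )
        cm, recs = read_annotations(p)
        assert cm.counts.shape == (2, 2)
        assert cm.counts.loc["r1", "AAA"] == 3
        assert cm.counts.loc["r1", "BBB"] == 0
        assert cm.counts.loc["r2", "AAA"] == 0
        assert {r.recording_id for r in recs} == {"r1", "r2"}
        assert recs[0].year == 2018  # parsed from the date

    def test_negative_count_rejected_naming_row(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text(
            "recording_id,site_id,date,species,count\nr1,s1,2018-06-01,AAA,-1\n"
        )
        with pytest.raises(ValidationError, match="r1"):
            read_annotations(p)

    def test_duplicate_pair_rejected(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text(
            "recording_id,site_id,date,species,count\n"
            "r1,s1,2018-06-01,AAA,1\nr1,s1,2018-06-01,AAA,2\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_annotations(p)

    def test_round_trip_preserves_generator_truth(self, tmp_path, default_sim):
        path = tmp_path / "sim.csv"
        write_annotations(default_sim.count_matrix, default_sim.recordings, path)
        cm, recs = read_annotations(path)
        pd.testing.assert_frame_equal(
            cm.counts.sort_index(axis=1),
            default_sim.count_matrix.counts.sort_index(axis=1).sort_index(),
            check_names=False,
        )
        assert cm.taxon_class == {
            s: "bird" for s in default_sim.count_matrix.counts.columns
        }


class TestSelectionTable:
    def test_rows_sorted_and_round_trip(self, tmp_path):
        p = tmp_path / "sel.txt"
        p.write_text(
            "Selection\tBegin Time (s)\tEnd Time (s)\tLow Freq (Hz)\tHigh Freq (Hz)\tSpecies\n"
            "1\t5.25\t6.10\t2000\t5000\tAAA\n"
            "2\t1.00\t2.50\t3000\t6000\tBBB\n"
            "3\t3.33\t4.00\t2500\t4500\tAAA\n"
        )
        table = read_selection_table(p)
        assert list(table.selections["begin_s"]) == [1.00, 3.33, 5.25]
        out = tmp_path / "roundtrip.txt"
        write_selection_table(table, out)
        again = read_selection_table(out)
        np.testing.assert_allclose(
            again.selections["begin_s"], table.selections["begin_s"], atol=0.01
        )
        np.testing.assert_allclose(
            again.selections["end_s"], table.selections["end_s"], atol=0.01
        )

    def test_end_before_begin_rejected(self, tmp_path):
        p = tmp_path / "sel.txt"
        p.write_text(
            "Selection\tBegin Time (s)\tEnd Time (s)\tSpecies\n9\t4.0\t3.0\tAAA\n"
        )
        with pytest.raises(ValidationError, match="9"):
            read_selection_table(p)


class TestSummaries:
    def test_totals_are_column_sums(self, toy_count_matrix, toy_recordings):
        summary = summarize_species(toy_count_matrix, toy_recordings, group_by="year")
        expected = toy_count_matrix.counts.sum(axis=0)
        for sp in toy_count_matrix.species:
            assert summary.loc[sp, "total"] == expected[sp]
        assert summary["total"].is_monotonic_decreasing

    def test_per_recording_species_count(self, toy_count_matrix):
        rec = ingest.recording_summary(toy_count_matrix)
        assert rec.loc["r4", "species_detected"] == 3
        assert rec.loc["r3", "species_detected"] == 1
        assert rec.loc["r1", "total_vocalizations"] == 13

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            summarize_species(CountMatrix(pd.DataFrame()))


class TestDominanceShare:
    def test_single_species_is_everything(self):
        cm = CountMatrix(pd.DataFrame({"AAA": [5, 3]}, index=["r1", "r2"]))
        assert dominance_share(cm, top_k=1) == 100.0

    def test_all_species_is_everything(self, toy_count_matrix):
        assert dominance_share(toy_count_matrix, top_k=3) == 100.0

    def test_named_species_with_taxon_exclusion(self, toy_count_matrix):
        # mammal CCC (26 calls) excluded: AAA share = 8 / 15
        assert dominance_share(
            toy_count_matrix, species="AAA", exclude_taxa=("mammal",)
        ) == pytest.approx(53.3)

    def test_top_k_exceeding_species_count_rejected(self, toy_count_matrix):
        with pytest.raises(ValidationError):
            dominance_share(toy_count_matrix, top_k=10)


class TestPairwiseDistances:
    def test_identical_coordinates_zero(self):
        sites = [Site("a", 44.0, -71.0), Site("b", 44.0, -71.0)]
        assert pairwise_distances(sites).loc["a", "b"] == pytest.approx(0.0)

    def test_small_latitude_offset_closed_form(self):
        # 0.001 deg of latitude = R * 0.001 * pi/180 = 111.19 m at R = 6371 km
        sites = [Site("a", 44.0, -71.0), Site("b", 44.001, -71.0)]
        d = pairwise_distances(sites).loc["a", "b"]
        assert d == pytest.approx(111.2, abs=0.1)

    def test_symmetry_and_missing_coordinates(self, square_sites):
        dm = pairwise_distances(square_sites)
        pd.testing.assert_frame_equal(dm, dm.T)
        with pytest.raises(ValidationError, match="bad"):
            pairwise_distances(square_sites + [Site("bad", float("nan"), 0.0)])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-80, max_value=80),
                st.floats(min_value=-179, max_value=179),
            ),
            min_size=3, max_size=3,
        )
    )
    def test_triangle_inequality(self, coords):
        sites = [Site(f"s{i}", lat, lon) for i, (lat, lon) in enumerate(coords)]
        d = pairwise_distances(sites).to_numpy()
        assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-6


class TestExclusions:
    def _recs(self, n_dates, rainy):
        recs = []
        for i in range(n_dates):
            date = f"2018-06-{i + 1:02d}"
            recs.append(Recording(f"r{i}", "s1", date,
                                  rain_rank=4 if date in rainy else 0))
        return recs

    def test_two_rain_dates_leave_nineteen(self):
        rainy = {"2018-06-04", "2018-06-11"}
        out = apply_exclusions(self._recs(21, rainy), max_rain_rank=2)
        kept_dates = {r.date for r in retained(out)}
        assert len(kept_dates) == 19
        assert rainy.isdisjoint(kept_dates)

    def test_permissive_threshold_excludes_nothing(self):
        out = apply_exclusions(self._recs(5, set()), max_rain_rank=4)
        assert all(not r.excluded for r in out)

    def test_strict_threshold_excludes_all(self):
        recs = [Recording(f"r{i}", "s1", "2018-06-01", rain_rank=4) for i in range(3)]
        out = apply_exclusions(recs, max_rain_rank=0)
        assert all(r.excluded for r in out)

    def test_explicit_dates(self):
        out = apply_exclusions(self._recs(5, set()), max_rain_rank=4,
                               explicit_dates={"2018-06-03"})
        assert sum(r.excluded for r in out) == 1


class TestRepeatability:
    def _matrix(self, arr):
        return CountMatrix(pd.DataFrame(
            arr, index=[f"r{i}" for i in range(len(arr))], columns=["AAA", "BBB"]
        ))

    def test_identical_passes(self):
        cm = self._matrix([[3, 1], [5, 0], [2, 2]])
        r2, same = repeatability(cm, cm)
        assert (r2["r2"] == 1.0).all()
        assert same.all()

    def test_noise_reduces_r2_monotonically(self):
        rng = np.random.default_rng(7)
        base = rng.poisson(30, size=(30, 2))
        first = self._matrix(base)
        r2_low, _ = repeatability(first, self._matrix(
            np.maximum(base + rng.integers(-1, 2, base.shape), 0)))
        r2_high, _ = repeatability(first, self._matrix(
            np.maximum(base + rng.integers(-8, 9, base.shape), 0)))
        assert r2_low["r2"].mean() < 1.0
        assert r2_high["r2"].mean() < r2_low["r2"].mean()

    def test_zero_variance_species_reported_missing(self):
        first = self._matrix([[3, 5], [3, 2], [3, 7]])  # AAA constant
        second = self._matrix([[3, 5], [3, 3], [3, 6]])
        r2, _ = repeatability(first, second)
        assert np.isnan(r2.loc["AAA", "r2"])
        assert not np.isnan(r2.loc["BBB", "r2"])

    def test_disjoint_recordings_rejected(self):
        a = self._matrix([[1, 2]])
        b = CountMatrix(pd.DataFrame([[1, 2]], index=["zz"], columns=["AAA", "BBB"]))
        with pytest.raises(ValidationError):
            repeatability(a, b)


def test_round_trip_preserves_counts_property(tmp_path):
    """Any generated dataset survives the disk round trip exactly."""
    for seed in (0, 1):
        sim = simulate_counts(CommunitySpec(), seed=seed)
        p = tmp_path / f"rt{seed}.csv"
        write_annotations(sim.count_matrix, sim.recordings, p)
        cm, _ = read_annotations(p)
        assert cm.counts.sort_index(axis=1).equals(
            sim.count_matrix.counts.sort_index().sort_index(axis=1)
        )
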