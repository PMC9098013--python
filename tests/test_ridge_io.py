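"""Ridge table I/O, gap filling, feature matching, and channel scaling."""

import numpy as np
import pytest

from ridgenet import ridge_io
from ridgenet.ridge_io import (
    AnnotationRecord,
    Experiment,
    Ridge,
    RidgeCollection,
    TimeGrid,
    fill_gaps,
    match_features,
    normalize_hsqc,
    read_ridge_table,
    scale_for_comparison,
    write_ridge_table,
)

from conftest import make_experiment, make_ridge


class TestTimeGrid:
    def test_rejects_short_and_unsorted(self):
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.0, 1.0, 2.0]))
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.0, 2.0, 1.0, 3.0]))

    def test_domain(self):
        g = TimeGrid(np.array([0.0, 0.5, 1.5, 4.0]))
        assert g.domain == (0.0, 4.0)


class TestTableRoundTrip:
    def test_round_trip_bit_exact(self, tmp_path, two_experiment_collection):
        p = tmp_path / "ridges.tsv"
        write_ridge_table(two_experiment_collection, p)
        coll2 = read_ridge_table(p)
        assert sorted(coll2.experiments) == ["expA", "expB"]
        for eid, exp in two_experiment_collection.experiments.items():
            exp2 = coll2.experiments[eid]
            assert np.array_equal(exp.grid.times, exp2.grid.times)
            for fid, r in exp.ridges.items():
                r2 = exp2.ridges[fid]
                assert np.array_equal(r.intensity_trace, r2.intensity_trace)
                assert np.array_equal(r.ppm_trace, r2.ppm_trace)

    def test_toy_file_shape(self, tmp_path):
        p = tmp_path / "toy.tsv"
        lines = ["experiment_id\tfeature_id\ttime\tppm\tintensity"]
        for fid in ("a", "b"):
            for i, t in enumerate(range(5)):
                lines.append(f"e1\t{fid}\t{t}\t1.5\t{i + 1}")
        p.write_text("\n".join(lines) + "\n")
        coll = read_ridge_table(p)
        assert len(coll) == 1
        exp = coll.experiments["e1"]
        assert len(exp) == 2
        assert len(exp.grid) == 5

    def test_gap_is_missing_not_zero(self, tmp_path):
        p = tmp_path / "gap.tsv"
        rows = ["experiment_id\tfeature_id\ttime\tppm\tintensity"]
        for t in range(5):
            inten = "" if t == 3 else str(float(t))
            rows.append(f"e1\tf\t{t}\t1.0\t{inten}")
        p.write_text("\n".join(rows) + "\n")
        ridge = read_ridge_table(p).experiments["e1"].ridges["f"]
        assert np.isnan(ridge.intensity_trace[3])
        assert ridge.intensity_trace[2] == 2.0

    def test_duplicate_times_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        rows = ["experiment_id\tfeature_id\ttime\tppm\tintensity"]
        rows += [f"e1\tf\t{t}\t1.0\t1.0" for t in (0, 1, 1, 2, 3)]
        p.write_text("\n".join(rows) + "\n")
        with pytest.raises(ridge_io.RidgeTableError):
            read_ridge_table(p)


class TestMatImport:
    def test_synthetic_container_round_trip(self, tmp_path):
        """A synthetic MATLAB container with per-ridge time/ppm/intensity
        structs maps onto the canonical model."""
        from scipy.io import savemat

        rng = np.random.default_rng(0)
        ridges = np.empty((4,), dtype=object)
        for i in range(4):
            ridges[i] = {
                "time": np.arange(0, 6, 1.0),
                "ppm": np.full(6, 1.0 + 0.1 * i),
                "intensity": rng.uniform(0, 1, 6),
            }
        p = tmp_path / "ridges.mat"
        savemat(p, {"ridges": ridges})
        coll = ridge_io.read_mat_ridges(p, experiment_id="e1")
        exp = coll.experiments["e1"]
        assert len(exp) == 4
        assert len(exp.grid) == 6

    def test_unrecognized_container_errors(self, tmp_path):
        from scipy.io import savemat

        p = tmp_path / "junk.mat"
        savemat(p, {"x": np.arange(3)})
        with pytest.raises(ridge_io.RidgeTableError):
            ridge_io.read_mat_ridges(p)


class TestFillGaps:
    def test_nearest_fill_with_earlier_tie(self):
        r = make_ridge("f", "e", [np.nan, 2, np.nan, 4, np.nan])
        filled = fill_gaps(r)
        # t=3 (index 2) is equidistant from index 1 and 3: earlier wins
        assert filled.intensity_trace.tolist() == [2, 2, 2, 4, 4]
        assert filled.fill_mask.tolist() == [True, False, True, False, True]

    def test_identity_on_complete_ridge(self):
        r = make_ridge("f", "e", [1.0, 2, 3, 4, 5])
        filled = fill_gaps(r)
        assert np.array_equal(filled.intensity_trace, r.intensity_trace)
        assert not filled.fill_mask.any()

    def test_idempotent(self):
        r = make_ridge("f", "e", [np.nan, 2, np.nan, 4, 5])
        once = fill_gaps(r)
        twice = fill_gaps(once)
        assert np.array_equal(once.intensity_trace, twice.intensity_trace)

    def test_all_missing_errors(self):
        r = make_ridge("f", "e", [np.nan] * 5)
        with pytest.raises(ValueError):
            fill_gaps(r)

    def test_matches_bruteforce_nearest_lookup(self):
        rng = np.random.default_rng(7)
        n = 40
        vals = rng.uniform(1, 10, n)
        mask = rng.random(n) < 0.2
        mask[rng.integers(n)] = False  # keep at least one present
        y = vals.copy()
        y[mask] = np.nan
        filled = fill_gaps(make_ridge("f", "e", y))
        present = np.flatnonzero(~mask)
        for i in range(n):
            dist = np.abs(present - i)
            j = present[np.argmin(dist)]  # first minimum = earlier index
            assert filled.intensity_trace[i] == vals[j] or not mask[i]


class TestMatchFeatures:
    def _coll(self, ppms_a, ppms_b, compounds_a=None, compounds_b=None):
        t = [0.0, 1, 2, 3]
        coll = RidgeCollection()
        specs_a = [
            (f"a{i}", [1, 2, 3, 4], p, (compounds_a or {}).get(i))
            for i, p in enumerate(ppms_a)
        ]
        specs_b = [
            (f"b{i}", [1, 2, 3, 4], p, (compounds_b or {}).get(i))
            for i, p in enumerate(ppms_b)
        ]
        coll.add(make_experiment("A", t, specs_a))
        coll.add(make_experiment("B", t, specs_b))
        return coll

    def test_identical_ppm_matches(self):
        table = match_features(self._coll([1.480], [1.480]))
        assert len(table.groups) == 1
        assert len(table.groups[0].members) == 2

    def test_beyond_threshold_rejected(self):
        table = match_features(self._coll([1.480], [1.495]))
        assert table.groups == []

    def test_annotated_matched_by_compound(self):
        # drift 0.02 ppm > threshold, but shared compound name matches
        table = match_features(
            self._coll([1.480], [1.500], {0: "alanine"}, {0: "alanine"})
        )
        assert len(table.groups) == 1
        assert table.groups[0].compound == "alanine"

    def test_annotated_different_compounds_never_match(self):
        table = match_features(
            self._coll([1.480], [1.480], {0: "alanine"}, {0: "lactate"})
        )
        assert table.groups == []

    def test_greedy_matches_bruteforce_oracle(self):
        """Conflicting distances resolve exactly as greedy ascending order."""
        ppms_a = [1.000, 1.004, 1.009]
        ppms_b = [1.002, 1.005, 1.020]
        table = match_features(self._coll(ppms_a, ppms_b))

        # brute-force greedy oracle on all cross pairs
        pairs = []
        for i, pa in enumerate(ppms_a):
            for j, pb in enumerate(ppms_b):
                d = abs(pa - pb)
                if d <= 0.01:
                    pairs.append((d, min(pa, pb), i, j))
        pairs.sort()
        used_a, used_b, expected = set(), set(), set()
        for _, _, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            expected.add((f"a{i}", f"b{j}"))
        got = {
            tuple(f for _, f in g.members)
            for g in table.groups
        }
        assert got == {(a, b) for a, b in expected}

    def test_symmetric_in_experiment_order(self):
        ppms_a = [1.000, 1.004]
        ppms_b = [1.002, 1.005]
        t1 = match_features(self._coll(ppms_a, ppms_b))
        # swap: same features, experiments renamed
        t = [0.0, 1, 2, 3]
        coll = RidgeCollection()
        coll.add(make_experiment("B", t, [(f"b{i}", [1, 2, 3, 4], p) for i, p in enumerate(ppms_b)]))
        coll.add(make_experiment("A", t, [(f"a{i}", [1, 2, 3, 4], p) for i, p in enumerate(ppms_a)]))
        t2 = match_features(coll)
        sets1 = {frozenset(g.members) for g in t1.groups}
        sets2 = {frozenset(g.members) for g in t2.groups}
        assert sets1 == sets2


class TestNormalizeHsqc:
    def _channels(self, proton_traces, hsqc_trace, n=8):
        t = np.linspace(0, 7, n)
        proton = make_experiment(
            "p", t, [(f"pyr{i}", tr, 2.37) for i, tr in enumerate(proton_traces)]
        )
        hsqc = make_experiment("h", t, [("pyrH", hsqc_trace, 2.37)])
        return proton, hsqc

    def test_identity_factor(self):
        tr = np.linspace(10, 3, 8)
        proton, hsqc = self._channels([tr / 4] * 4, tr)
        factor, rescaled = normalize_hsqc(proton, hsqc, [f"pyr{i}" for i in range(4)], "pyrH")
        assert factor == pytest.approx(1.0)
        assert np.allclose(rescaled.ridges["pyrH"].intensity_trace, tr)

    def test_constant_ratio(self):
        tr = np.linspace(10, 3, 8)
        proton, hsqc = self._channels([tr * 2.5 / 4] * 4, tr)
        factor, _ = normalize_hsqc(proton, hsqc, [f"pyr{i}" for i in range(4)], "pyrH")
        assert factor == pytest.approx(2.5)

    def test_quantile_filtered_mean_oracle(self):
        rng = np.random.default_rng(3)
        n = 20
        t = np.linspace(0, 10, n)
        hs = 10 * np.exp(-0.4 * t) + 0.05  # decaying pyruvate
        ratios = 2.0 + 0.1 * rng.standard_normal(n)
        proton_sum = hs * ratios
        proton, hsqc = self._channels([proton_sum / 4] * 4, hs, n)
        factor, _ = normalize_hsqc(proton, hsqc, [f"pyr{i}" for i in range(4)], "pyrH")
        keep = (proton_sum > np.quantile(proton_sum, 0.10)) & (hs > np.quantile(hs, 0.10))
        assert factor == pytest.approx(np.mean(proton_sum[keep] / hs[keep]))

    def test_invariant_to_joint_rescale(self):
        tr = np.linspace(10, 3, 8)
        p1, h1 = self._channels([tr / 2] * 4, tr)
        p2, h2 = self._channels([tr * 5] * 4, tr * 10)
        ids = [f"pyr{i}" for i in range(4)]
        f1, _ = normalize_hsqc(p1, h1, ids, "pyrH")
        f2, _ = normalize_hsqc(p2, h2, ids, "pyrH")
        assert f1 == pytest.approx(f2)


class TestScaleForComparison:
    def test_unlabeled_self_normalization(self):
        r = make_ridge("u", "e1", [2.0, 5, 10, 4])
        out = scale_for_comparison({"glc": {"unlabeled": [r]}})
        vals = out["glc"][0].values
        # after dividing by its own max, the pre-standardization max is 1
        assert np.nanstd(vals, ddof=1) == pytest.approx(1.0)
        assert np.nanmean(vals) == pytest.approx(0.0, abs=1e-12)

    def test_constant_ridge_flagged(self):
        u = make_ridge("u", "e1", [1.0, 2, 3, 4])
        c = make_ridge("c", "e2", [5.0, 5, 5, 5])
        out = scale_for_comparison({"glc": {"unlabeled": [u], "labeled": [c]}})
        flags = {s.ridge.feature_id: s.zero_variance for s in out["glc"]}
        assert flags["c"] is True
        assert flags["u"] is False

    def test_zero_unlabeled_max_errors(self):
        r = make_ridge("u", "e1", [0.0, 0, 0, 0])
        with pytest.raises(ValueError, match="glc"):
            scale_for_comparison({"glc": {"unlabeled": [r]}})

    def test_two_strata_standardized_independently(self):
        u = make_ridge("u", "e1", [1.0, 4, 2, 8])
        l1 = make_ridge("l", "e1", [0.5, 1, 2, 4], labeled=True)
        out = scale_for_comparison({"glc": {"unlabeled": [u], "labeled": [l1]}})
        for s in out["glc"]:
            assert np.nanmean(s.values) == pytest.approx(0.0, abs=1e-12)
            assert np.nanstd(s.values, ddof=1) == pytest.approx(1.0)
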