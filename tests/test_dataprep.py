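"""Scaling relations, structure filters, diversity sampling, IQR cleaning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shiftgnn import dataprep
from shiftgnn import synthetic as syn
from shiftgnn.molio import Molecule, ShiftRecord


class TestScaling:
    def test_affine_property(self):
        rel = dataprep.ScalingRelation(100.0, 2.0, "C13")
        s1, s2 = 13.7, -4.2
        assert rel(s1) - rel(s2) == pytest.approx(-2.0 * (s1 - s2))

    @given(st.floats(min_value=-300, max_value=300))
    @settings(deadline=None, derandomize=True)
    def test_c13_relation_closed_form(self, sigma):
        assert dataprep.scale_shielding(sigma, dataprep.C13_SCALING) == pytest.approx(
            181.40 - 0.97 * sigma, rel=1e-12, abs=1e-9
        )

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            dataprep.ScalingRelation(100.0, -1.0, "C13")


def _mol(mol_id, elements, charge=0, mw=100.0, stereo=()):
    return Molecule(
        id=mol_id,
        elements=elements,
        formal_charges=[charge] + [0] * (len(elements) - 1),
        stereo_defined=list(stereo),
        mol_weight=mw,
    )


class TestFilter:
    def test_rejection_reasons(self):
        mols = [
            _mol("ok", ["C", "H"]),
            _mol("cation", ["N", "H"], charge=1),
            _mol("heavy", ["C", "H"], mw=512.3),
            _mol("boundary", ["C", "H"], mw=499.9),
            _mol("brominated", ["C", "Br"]),
        ]
        report = dataprep.filter_structures(mols)
        assert [m.id for m in report.kept] == ["ok", "boundary"]
        assert report.rejected == {
            "charge": ["cation"],
            "mol_weight": ["heavy"],
            "element": ["brominated"],
        }

    def test_stereo_requirement_optional(self):
        amb = _mol("ambiguous", ["C", "H"], stereo=(True, False))
        assert dataprep.filter_structures([amb]).kept == [amb]
        report = dataprep.filter_structures([amb], require_stereo_defined=True)
        assert report.rejected == {"stereo": ["ambiguous"]}


def _greedy_oracle(fps, k, first):
    """Independent brute-force greedy max-min selection."""

    def jaccard_dist(a, b):
        union = np.logical_or(a, b).sum()
        if union == 0:
            return 0.0
        return 1.0 - np.logical_and(a, b).sum() / union

    selected = [first]
    while len(selected) < k:
        best_i, best_d = None, -1.0
        for i in range(len(fps)):
            if i in selected:
                continue
            d = min(jaccard_dist(fps[i], fps[j]) for j in selected)
            if d > best_d:
                best_i, best_d = i, d
        selected.append(best_i)
    return selected


class TestFarthestNeighbor:
    def test_k_equals_n_selects_everything(self):
        fps = np.random.default_rng(0).integers(0, 2, (7, 32)).astype(bool)
        assert sorted(dataprep.farthest_neighbor_sample(fps, 7, seed=1)) == list(range(7))

    def test_k_one_is_the_seeded_pick_only(self):
        fps = np.random.default_rng(0).integers(0, 2, (7, 32)).astype(bool)
        sel = dataprep.farthest_neighbor_sample(fps, 1, seed=1)
        assert len(sel) == 1

    def test_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            fps = rng.integers(0, 2, (6, 32)).astype(bool)
            got = dataprep.farthest_neighbor_sample(fps, 3, seed=trial)
            assert got == _greedy_oracle(fps, 3, got[0])

    def test_no_duplicates_and_monotone_minimum_distance(self):
        rng = np.random.default_rng(3)
        fps = rng.integers(0, 2, (20, 64)).astype(bool)
        sel = dataprep.farthest_neighbor_sample(fps, 20, seed=9)
        assert len(set(sel)) == 20

        def min_pairwise(sub):
            ds = []
            for a in range(len(sub)):
                for b in range(a + 1, len(sub)):
                    inter = (fps[sub[a]] & fps[sub[b]]).sum()
                    union = (fps[sub[a]] | fps[sub[b]]).sum()
                    ds.append(1.0 - inter / union)
            return min(ds)

        prev = np.inf
        for k in range(2, 21):
            cur = min_pairwise(sel[:k])
            assert cur <= prev + 1e-12
            prev = cur

    def test_k_out_of_range_rejected(self):
        fps = np.zeros((3, 8), dtype=bool)
        with pytest.raises(ValueError):
            dataprep.farthest_neighbor_sample(fps, 4)


def _pairs_from_diffs(diffs, nucleus="C13"):
    out = []
    for i, d in enumerate(diffs):
        exp = ShiftRecord(f"m{i}", 0, nucleus, 100.0, "experimental")
        comp = ShiftRecord(f"m{i}", 0, nucleus, 100.0 + d, "computed")
        out.append((comp, exp))
    return out


class TestIQRCleaning:
    def test_all_equal_differences_all_kept(self):
        report = dataprep.clean_by_iqr(_pairs_from_diffs([2.0] * 10))
        assert report.iqr == 0.0
        assert report.kept.all()

    def test_gross_outlier_removed_with_linear_quartiles(self):
        diffs = list(range(1, 101)) + [1000.0]
        report = dataprep.clean_by_iqr(_pairs_from_diffs(diffs))
        assert report.q1 == pytest.approx(26.0)
        assert report.q3 == pytest.approx(76.0)
        removed = np.flatnonzero(~report.kept)
        assert list(removed) == [100]
        assert report.rmse_after < report.rmse_before

    def test_removed_fraction_invariant_under_constant_offset(self):
        rng = np.random.default_rng(8)
        diffs = rng.normal(0, 2, 500)
        diffs[:20] += 25.0
        r1 = dataprep.clean_by_iqr(_pairs_from_diffs(list(diffs)))
        r2 = dataprep.clean_by_iqr(_pairs_from_diffs(list(diffs + 7.3)))
        np.testing.assert_array_equal(r1.kept, r2.kept)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            dataprep.clean_by_iqr(_pairs_from_diffs([1.0, 2.0, 3.0]))

    def test_mixed_nuclei_rejected(self):
        pairs = _pairs_from_diffs([1.0, 2.0, 3.0, 4.0])
        bad = _pairs_from_diffs([1.0], nucleus="H1")
        with pytest.raises(ValueError, match="nuclei"):
            dataprep.clean_by_iqr(pairs + bad)

    def test_contaminated_fixture_cleanup(self):
        pairs = syn.make_contaminated_pairs(2000, sigma=2.0, outlier_frac=0.05,
                                            outlier_mag=15.0, seed=11)
        report = dataprep.clean_by_iqr(list(zip(pairs.computed, pairs.experimental)))
        removed = set(np.flatnonzero(~report.kept))
        hit = len(removed & set(pairs.planted_outliers)) / len(pairs.planted_outliers)
        assert hit >= 0.95
        assert report.rmse_after < report.rmse_before


class TestSplit:
    def test_default_sizes(self):
        ids = [f"m{i}" for i in range(1100)]
        train, val, test = dataprep.split_dataset(ids, seed=4)
        assert (len(train), len(val), len(test)) == (100, 500, 500)

    def test_deterministic_partition(self):
        ids = [f"m{i}" for i in range(50)]
        a = dataprep.split_dataset(ids, n_val=10, n_test=10, seed=2)
        b = dataprep.split_dataset(ids, n_val=10, n_test=10, seed=2)
        assert a == b
        union = set(a[0]) | set(a[1]) | set(a[2])
        assert union == set(ids)
        assert len(a[0]) + len(a[1]) + len(a[2]) == 50

    def test_insufficient_ids_rejected(self):
        with pytest.raises(ValueError):
            dataprep.split_dataset(["a", "b"], n_val=1, n_test=1)


def test_match_pairs_by_key():
    comp = [ShiftRecord("m1", 0, "C13", 10.0, "computed"),
            ShiftRecord("m1", 1, "C13", 20.0, "computed")]
    exp = [ShiftRecord("m1", 1, "C13", 21.0, "experimental")]
    pairs = dataprep.match_pairs(comp, exp)
    assert len(pairs) == 1
    assert pairs[0][0].atom_index == 1
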