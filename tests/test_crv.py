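import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsslearn.crv import (
    COMBOS,
    REFERENCE_CRV_GROUPINGS,
    all_crvs,
    covariation_distance,
    covariation_groups,
    cumulative_curve,
    fit_crv,
    partition_modes,
    quadrant_census,
    sweep_offset,
)
from rsslearn.explain import AttributionMatrix


def jittered_cloud(center, n=50, spread=0.01, seed=0):
    rng = np.random.default_rng(seed)
    return np.asarray(center) + rng.normal(0, spread, size=(n, 2))


@pytest.fixture(scope="module")
def random_attr(h4s2_encoding):
    """Synthetic attribution matrix over the full library: each feature's
    attribution depends on its bit plus noise, giving realistic
    origin-anchored modes."""
    rng = np.random.default_rng(6)
    enc = h4s2_encoding.iloc[:1024]
    effects = rng.normal(0, 0.1, size=24)
    vals = (enc.to_numpy(dtype=float) - 0.25) * effects + \
        rng.normal(0, 0.01, size=(1024, 24))
    values = pd.DataFrame(vals, index=enc.index, columns=enc.columns)
    return AttributionMatrix(values=values, base_prediction=0.1), enc


class TestFitCRV:
    def test_three_four_five_triangle(self):
        rng = np.random.default_rng(0)
        # |x| 99th percentile ~3, |y| ~4 by construction
        pts = np.column_stack([rng.uniform(2.99, 3.0, 500),
                               rng.uniform(3.99, 4.0, 500)])
        rec = fit_crv(pts, (1, 1), "f1", "f2")
        assert rec.length == pytest.approx(5.0, abs=0.01)

    def test_q1_cluster(self):
        rec = fit_crv(jittered_cloud((0.5, 0.5)), (1, 1), "a", "b")
        assert rec.quadrant == "Q1"
        assert rec.angle_deg == pytest.approx(45.0, abs=3.0)

    def test_q3_cluster(self):
        rec = fit_crv(jittered_cloud((-0.5, -0.5)), (0, 0), "a", "b")
        assert rec.quadrant == "Q3"
        assert rec.angle_deg == pytest.approx(225.0, abs=3.0)

    @pytest.mark.parametrize("center,quadrant", [
        ((0.5, -0.5), "Q4"), ((-0.5, 0.5), "Q2"),
    ])
    def test_antagonistic_quadrants(self, center, quadrant):
        assert fit_crv(jittered_cloud(center), (1, 0), "a", "b").quadrant == quadrant

    def test_degenerate_modes(self):
        assert fit_crv(np.empty((0, 2)), (1, 1), "a", "b").length == 0.0
        one = fit_crv(np.array([[1.0, 2.0]]), (1, 1), "a", "b")
        assert one.degenerate and one.length == 0.0
        same = fit_crv(np.tile([[1.0, 2.0]], (5, 1)), (1, 1), "a", "b")
        assert same.degenerate

    def test_axis_dominated_tag(self):
        rec = fit_crv(jittered_cloud((0.5, 0.02), spread=0.002), (1, 0), "a", "b")
        assert rec.axis_dominated
        mid = fit_crv(jittered_cloud((0.5, 0.5)), (1, 1), "a", "b")
        assert not mid.axis_dominated

    def test_pc1_slope_matches_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        pts = rng.normal(size=(200, 2)) @ np.array([[1.0, 0.7], [0.0, 0.4]])
        rec = fit_crv(pts, (1, 1), "a", "b")
        v = PCA(n_components=1).fit(pts).components_[0]
        assert rec.slope == pytest.approx(v[1] / v[0], rel=1e-6)


class TestPartitionModes:
    def test_same_position_pair_has_empty_11(self, random_attr):
        attr, enc = random_attr
        modes = partition_modes(attr, enc, "H4_A", "H4_T")
        assert len(modes[(1, 1)]) == 0

    def test_mode_sizes_cross_position(self, h4s2_encoding):
        attr = AttributionMatrix(
            values=h4s2_encoding.astype(float) * 0.0,
            base_prediction=0.0,
        )
        modes = partition_modes(attr, h4s2_encoding, "H6_T", "H7_G")
        # 3*3*4^4 / 3*4^4 / 3*4^4 / 4^4
        assert {c: len(p) for c, p in modes.items()} == {
            (0, 0): 2304, (0, 1): 768, (1, 0): 768, (1, 1): 256}

    def test_partition_covers_all_samples(self, random_attr):
        attr, enc = random_attr
        modes = partition_modes(attr, enc, "H5_C", "S2_G")
        assert sum(len(p) for p in modes.values()) == len(attr.values)

    def test_errors(self, random_attr):
        attr, enc = random_attr
        with pytest.raises(ValueError):
            partition_modes(attr, enc, "H4_A", "H4_A")
        with pytest.raises(KeyError):
            partition_modes(attr, enc, "H4_A", "nope")


@pytest.fixture(scope="module")
def crvs_small(random_attr):
    attr, enc = random_attr
    feats = ["H4_A", "H4_T", "H6_T", "H6_G", "H7_G", "H7_C"]
    return all_crvs(attr, enc, features=feats), feats


class TestAllCRVs:

    def test_record_count(self, crvs_small):
        crvs, feats = crvs_small
        # ordered pairs: 30; same-position pairs (6 ordered) lose the (1,1) combo
        assert len(crvs) == 30 * 4 - 6

    def test_no_same_position_11(self, crvs_small):
        crvs, _ = crvs_small
        same = crvs[(crvs["feature1"].str[:2] == crvs["feature2"].str[:2])
                    & (crvs["combo"] == "1,1")]
        assert same.empty

    def test_mirror_symmetry_exhaustive(self, crvs_small):
        """Swapping the pair (and transposing the combo) preserves length
        and reflects the angle across the 45-225 degree diagonal."""
        crvs, _ = crvs_small
        key = crvs.set_index(["feature1", "feature2", "combo"])
        for (f1, f2, combo), row in key.iterrows():
            c1, c2 = combo.split(",")
            mirror = key.loc[(f2, f1, f"{c2},{c1}")]
            assert mirror["length"] == pytest.approx(row["length"], rel=1e-9)
            if row["length"] > 0:
                expected = (90.0 - row["angle_deg"]) % 360.0
                assert mirror["angle_deg"] == pytest.approx(expected, abs=1e-6)

    def test_quadrant_consistent_with_angle(self, crvs_small):
        crvs, _ = crvs_small
        for _, row in crvs[crvs["length"] > 0].iterrows():
            a = row["angle_deg"] % 360
            if a % 90 == 0:
                assert row["quadrant"] == "axis"
            else:
                assert row["quadrant"] == "Q" + str(int(a // 90) + 1)

    def test_census_conserves_total(self, crvs_small):
        crvs, _ = crvs_small
        census = quadrant_census(crvs)
        assert census["n_crvs"].sum() == len(crvs)


class TestLengthInvariance:
    def test_point_order_and_duplication(self):
        # order invariance is exact; duplication invariance is asymptotic
        # under the linear-interpolation percentile convention
        rng = np.random.default_rng(2)
        pts = rng.normal(0.2, 0.1, size=(500, 2))
        base = fit_crv(pts, (1, 1), "a", "b").length
        shuffled = fit_crv(pts[rng.permutation(500)], (1, 1), "a", "b").length
        doubled = fit_crv(np.vstack([pts, pts]), (1, 1), "a", "b").length
        assert shuffled == pytest.approx(base, rel=1e-12)
        assert doubled == pytest.approx(base, rel=5e-3)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_mirror_property_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(rng.normal(0, 0.3, 2), 0.05, size=(30, 2))
        fwd = fit_crv(pts, (1, 0), "a", "b")
        rev = fit_crv(pts[:, ::-1], (0, 1), "b", "a")
        assert rev.length == pytest.approx(fwd.length, rel=1e-9)
        if fwd.length > 0:
            assert rev.angle_deg == pytest.approx(
                (90.0 - fwd.angle_deg) % 360.0, abs=1e-6)


class TestCumulativeCurve:
    def test_single_crv_at_sweep_origin(self):
        crvs = pd.DataFrame([{"feature1": "H4_A", "feature2": "H5_T",
                              "combo": "1,1", "length": 2.0,
                              "angle_deg": 225.0}])
        curve = cumulative_curve(crvs)
        assert curve["sweep_angle"].iloc[0] == 0.0
        assert curve["cumulative_length"].iloc[-1] == 2.0

    def test_nondecreasing_and_conserving(self, random_attr):
        attr, enc = random_attr
        crvs = all_crvs(attr, enc, features=["H4_A", "H4_T", "H6_T", "H7_G"])
        curves = cumulative_curve(crvs)
        for group, sub in curves.groupby("group"):
            assert (sub["cumulative_length"].diff().dropna() >= 0).all()
            total = crvs.loc[crvs["feature1"] == group, "length"].sum()
            assert sub["cumulative_length"].iloc[-1] == pytest.approx(total)

    def test_q1_band_lies_at_sweep_135_to_225(self):
        # Q1 angles (0-90 deg) map to sweep offsets 135-225 from the
        # 225-degree origin
        assert sweep_offset(0.0) == 135.0
        assert sweep_offset(90.0) == 225.0


class TestCovariation:
    def _curve(self, name, angles, lengths):
        crvs = pd.DataFrame({
            "feature1": name, "feature2": "X_Y", "combo": "1,1",
            "length": lengths, "angle_deg": angles,
        })
        return cumulative_curve(crvs)

    def test_identical_curves_distance_zero(self):
        a = self._curve("H4_A", [10, 100, 250], [1, 2, 3])
        b = self._curve("H4_T", [10, 100, 250], [1, 2, 3])
        assert covariation_distance(a, b) == 0.0

    def test_scaled_curves_distance_zero(self):
        # normalization by final value makes pure scaling invisible
        a = self._curve("H4_A", [10, 100, 250], [1, 2, 3])
        b = self._curve("H4_T", [10, 100, 250], [2, 4, 6])
        assert covariation_distance(a, b) == 0.0

    def test_planted_equivalence_grouped(self):
        curves = pd.concat([
            self._curve("H4_A", [30, 200], [1, 1]),
            self._curve("H4_T", [30, 200], [1.1, 0.9]),
            self._curve("H4_G", [120, 300], [2, 0.5]),
            self._curve("H4_C", [120, 300], [2.1, 0.4]),
        ])
        groups = covariation_groups(curves, threshold=0.15)
        assert sorted(groups) == ["S", "W"]  # {A,T} -> W, {G,C} -> S

    def test_reference_groupings_constants(self):
        assert REFERENCE_CRV_GROUPINGS["H6"] == ("R", "T", "C")
        assert REFERENCE_CRV_GROUPINGS["S1"] == ("W", "S")
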