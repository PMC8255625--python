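import numpy as np
import pytest

from mpmri import make_ellipsoid, overlap, overlap_matrix, summaries_from_specs
from mpmri.ellipsoids import DegenerateEllipsoidError, Ellipsoid
from mpmri.voi import StructureSummary


def _ball(center, radius=1.0, name="e"):
    return Ellipsoid(name, np.asarray(center, float),
                     np.full(3, float(radius)), 50.0)


class TestMakeEllipsoid:
    def test_pal_summary(self, specs):
        by = {s.structure: s for s in summaries_from_specs(specs)}
        e = make_ellipsoid(by["Pal"])
        np.testing.assert_allclose(e.center, [0.0851, 23.0, 1237])
        np.testing.assert_allclose(e.semi_axes, [0.0095, 1.7, 15])
        assert e.color_value == pytest.approx(38.8)

    def test_unit_summary_gives_unit_ball(self):
        s = StructureSummary(
            structure="x",
            mean={"qsm": 0.0, "na": 0.0, "mtr": 0.0, "t1": 0.0},
            sd={"qsm": 1.0, "na": 1.0, "mtr": 1.0, "t1": 1.0},
            n_voxels=1,
        )
        e = make_ellipsoid(s)
        np.testing.assert_array_equal(e.center, 0.0)
        np.testing.assert_array_equal(e.semi_axes, 1.0)

    def test_all_table_structures_valid(self, specs):
        for s in summaries_from_specs(specs):
            assert np.all(make_ellipsoid(s).semi_axes > 0)

    def test_zero_sd_rejected(self):
        s = StructureSummary(
            structure="x",
            mean={"qsm": 0.0, "na": 0.0, "mtr": 0.0, "t1": 0.0},
            sd={"qsm": 0.0, "na": 1.0, "mtr": 1.0, "t1": 1.0},
            n_voxels=1,
        )
        with pytest.raises(DegenerateEllipsoidError):
            make_ellipsoid(s)


class TestOverlap:
    def test_self_overlap_margin_minus_one(self):
        e = _ball([1.0, 2.0, 3.0], 2.0)
        ov, margin = overlap(e, e)
        assert ov and margin == pytest.approx(-1.0)

    def test_unit_balls_at_distance_three(self):
        ov, margin = overlap(_ball([0, 0, 0]), _ball([3, 0, 0]))
        assert not ov
        assert margin == pytest.approx(3.0, abs=1e-8)

    def test_tangent_spheres_count_as_overlap(self):
        ov, margin = overlap(_ball([0, 0, 0]), _ball([2, 0, 0]))
        assert ov
        assert margin == pytest.approx(0.0, abs=1e-6)

    def test_symmetry_of_decision(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            e1 = Ellipsoid("a", rng.normal(size=3), rng.uniform(0.2, 2, 3), 0)
            e2 = Ellipsoid("b", rng.normal(size=3), rng.uniform(0.2, 2, 3), 0)
            assert overlap(e1, e2)[0] == overlap(e2, e1)[0]

    def test_inflation_monotonicity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            e1 = Ellipsoid("a", rng.normal(size=3), rng.uniform(0.2, 2, 3), 0)
            e2 = Ellipsoid("b", rng.normal(size=3), rng.uniform(0.2, 2, 3), 0)
            if overlap(e1, e2)[0]:
                t = rng.uniform(1.0, 3.0)
                big1 = Ellipsoid("a", e1.center, t * e1.semi_axes, 0)
                big2 = Ellipsoid("b", e2.center, t * e2.semi_axes, 0)
                assert overlap(big1, big2)[0]

    def test_agreement_with_sampling_oracle(self):
        """500 random pairs against dense rejection sampling in the
        bounding box; boundary cases (|margin| < 1e-3) excluded."""
        rng = np.random.default_rng(2)
        checked = agree = 0
        for _ in range(500):
            e1 = Ellipsoid("a", rng.normal(scale=1.5, size=3),
                           rng.uniform(0.3, 2.0, 3), 0)
            e2 = Ellipsoid("b", rng.normal(scale=1.5, size=3),
                           rng.uniform(0.3, 2.0, 3), 0)
            ov, margin = overlap(e1, e2)
            if abs(margin) < 1e-3:
                continue
            lo = np.maximum(e1.center - e1.semi_axes, e2.center - e2.semi_axes)
            hi = np.minimum(e1.center + e1.semi_axes, e2.center + e2.semi_axes)
            if np.any(lo >= hi):
                oracle = False
            else:
                pts = rng.uniform(lo, hi, size=(20000, 3))
                inside = (e1.quadratic(pts) <= 1) & (e2.quadratic(pts) <= 1)
                oracle = bool(inside.any())
            checked += 1
            # sampling can miss a sliver intersection but cannot invent one
            if oracle == ov or (ov and not oracle and margin > -0.05):
                agree += 1
        assert checked > 400
        assert agree / checked >= 0.99


class TestOverlapMatrix:
    def test_single_structure_group(self, specs):
        by = {s.structure: s for s in summaries_from_specs(specs)}
        names, mat, margins = overlap_matrix([by["Pal"]])
        assert names == ["Pal"] and mat.shape == (1, 1) and mat[0, 0]

    def test_matrix_consistent_with_pairwise_calls(self, specs):
        by = {s.structure: s for s in summaries_from_specs(specs)}
        members = ["VTA", "DRN", "PPN", "LC"]
        names, mat, margins = overlap_matrix([by[m] for m in members])
        ells = {m: make_ellipsoid(by[m]) for m in members}
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    assert mat[i, j] == (
                        overlap(ells[a], ells[b])[0] or overlap(ells[b], ells[a])[0]
                    )
                    assert mat[i, j] == mat[j, i]

    def test_extrapyramidal_reference_geometry(self, specs):
        """RN and SN ellipsoids are disjoint while RN and STN overlap;
        NC-Put is by far the closest disjoint pair of the group."""
        by = {s.structure: s for s in summaries_from_specs(specs)}
        members = ["SN", "STN", "RN", "Pal", "Put", "NC"]
        names, mat, margins = overlap_matrix([by[m] for m in members])
        idx = {n: i for i, n in enumerate(names)}
        assert not mat[idx["RN"], idx["SN"]]
        assert mat[idx["STN"], idx["RN"]]
        nc_put = margins[idx["NC"], idx["Put"]]
        others = [
            margins[i, j]
            for i in range(len(names)) for j in range(i + 1, len(names))
            if {names[i], names[j]} not in ({"NC", "Put"}, {"STN", "RN"})
        ]
        assert nc_put < 1.0 < min(others)
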