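import numpy as np
import pytest

from mpmri import (
    CohortConfig,
    extract_voi,
    grand_means,
    pool_and_summarize,
    pooled_correlation,
    rank_structures,
    sample_subject,
    summaries_from_specs,
    summarize,
)
from mpmri.reference import CONTRASTS
from mpmri.voi import VoxelBlock, subject_blocks


def _toy_maps(shape, rng):
    return {c: rng.uniform(0, 10, size=shape) for c in CONTRASTS}


class TestExtractVoi:
    def test_single_voxel_label(self):
        rng = np.random.default_rng(0)
        maps = _toy_maps((3, 3, 3), rng)
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[1, 2, 0] = 1
        block = extract_voi(maps, labels, "NC")  # NC carries label 1
        assert block.n_voxels == 1
        for c in CONTRASTS:
            assert block.values[c][0] == maps[c][1, 2, 0]

    def test_count_conservation_on_synthetic_subject(self, specs):
        cfg = CohortConfig(seed=9)
        subj = sample_subject(specs, cfg, 4)
        block = extract_voi(subj.maps, subj.labels, "Put")
        assert block.n_voxels == cfg.counts(["Put"])["Put"]

    def test_matches_brute_force_voxel_scan(self, specs):
        subj = sample_subject(specs, CohortConfig(seed=10), 5)
        block = extract_voi(subj.maps, subj.labels, "RN")
        label = [s.name for s in specs].index("RN") + 1
        expected = {c: [] for c in CONTRASTS}
        for idx in np.ndindex(subj.labels.shape):  # lexicographic scan
            if subj.labels[idx] == label:
                for c in CONTRASTS:
                    expected[c].append(subj.maps[c][idx])
        for c in CONTRASTS:
            np.testing.assert_array_equal(block.values[c], expected[c])

    def test_absent_label_and_shape_mismatch(self):
        rng = np.random.default_rng(1)
        maps = _toy_maps((2, 2, 2), rng)
        labels = np.zeros((2, 2, 2), dtype=int)
        with pytest.raises(KeyError):
            extract_voi(maps, labels, "Pal")
        labels_bad = np.ones((2, 2, 3), dtype=int)
        with pytest.raises(ValueError, match="shape"):
            extract_voi(maps, labels_bad, "Pal")


def _block(values_by_contrast, structure="NC", subject="s0"):
    return VoxelBlock(
        subject_id=subject, structure=structure,
        values={c: np.asarray(v, dtype=float)
                for c, v in values_by_contrast.items()},
    )


class TestSummaries:
    def test_constant_block(self):
        b = _block({c: [7.0, 7.0, 7.0] for c in CONTRASTS})
        s = summarize(b)
        for c in CONTRASTS:
            assert s.mean[c] == 7.0 and s.sd[c] == 0.0

    def test_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        data = {c: rng.normal(size=50) for c in CONTRASTS}
        s = summarize(_block(data))
        for c in CONTRASTS:
            x = data[c]
            m = sum(x) / len(x)
            sd = np.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))
            assert s.mean[c] == pytest.approx(m)
            assert s.sd[c] == pytest.approx(sd)

    def test_pooling_equals_concatenation(self):
        rng = np.random.default_rng(3)
        blocks = [
            _block({c: rng.normal(size=n) for c in CONTRASTS}, subject=f"s{i}")
            for i, n in enumerate([10, 20, 30])
        ]
        pooled = pool_and_summarize(blocks)
        assert pooled.n_voxels == 60
        allv = np.concatenate([b.values["t1"] for b in blocks])
        assert pooled.mean["t1"] == pytest.approx(allv.mean())
        assert pooled.sd["t1"] == pytest.approx(allv.std(ddof=1))

    def test_single_voxel_sd_zero_with_warning(self):
        with pytest.warns(UserWarning, match="single-voxel"):
            s = summarize(_block({c: [1.0] for c in CONTRASTS}))
        assert all(s.sd[c] == 0.0 for c in CONTRASTS)

    def test_permutation_invariance(self, specs):
        subj = sample_subject(specs, CohortConfig(seed=12), 6)
        s1 = summarize(extract_voi(subj.maps, subj.labels, "Pal"))
        # permute voxels by permuting the whole flat volume consistently
        rng = np.random.default_rng(0)
        perm = rng.permutation(subj.labels.size)
        labels_p = subj.labels.ravel()[perm].reshape(subj.labels.shape)
        maps_p = {
            c: subj.maps[c].ravel()[perm].reshape(subj.labels.shape)
            for c in CONTRASTS
        }
        s2 = summarize(extract_voi(maps_p, labels_p, "Pal"))
        for c in CONTRASTS:
            assert s1.mean[c] == pytest.approx(s2.mean[c])
            assert s1.sd[c] == pytest.approx(s2.sd[c])


class TestRanking:
    def test_table_extremes(self, specs):
        ranked = rank_structures(summaries_from_specs(specs), "qsm")
        assert ranked[0].structure == "CP"    # lowest susceptibility
        assert ranked[-1].structure == "VP"   # highest susceptibility

    def test_ties_break_alphabetically_and_permutation(self, specs):
        summaries = summaries_from_specs(specs)
        for s in summaries:
            s.mean["mtr"] = 1.0  # force a full tie
        ranked = rank_structures(summaries, "mtr")
        names = [s.structure for s in ranked]
        assert names == sorted(names)
        assert sorted(names) == sorted(x.structure for x in summaries)


class TestGrandMeans:
    def test_printed_grand_means_within_half_percent(self, specs):
        gm = grand_means(summaries_from_specs(specs), "nuclei", specs)
        assert gm["na"][0] == pytest.approx(51.0, rel=0.005)
        assert gm["t1"][0] == pytest.approx(1448.5, rel=0.005)
        assert gm["qsm"][0] == pytest.approx(0.031, abs=0.001)
        assert gm["mtr"][0] == pytest.approx(22.0, rel=0.01)
        # spread across structure means (population SD)
        assert gm["na"][1] == pytest.approx(14.4, rel=0.02)
        assert gm["t1"][1] == pytest.approx(179, rel=0.02)

    def test_fiber_tract_subset(self, specs):
        gm = grand_means(summaries_from_specs(specs), "fiber_tracts", specs)
        assert gm["qsm"][0] == pytest.approx(-0.028, abs=0.002)
        assert gm["t1"][0] == pytest.approx(1231, rel=0.005)
        assert gm["mtr"][0] == pytest.approx(24, rel=0.01)
        # the reference's printed fiber sodium mean (42.4) sits 1.9% off
        # the mean of its own two tabulated rows (40.0, 46.4 -> 43.2)
        assert gm["na"][0] == pytest.approx(42.4, rel=0.02)

    def test_missing_structures_reported(self, specs):
        partial = summaries_from_specs(specs)[:5]
        with pytest.raises(ValueError, match="missing"):
            grand_means(partial, "nuclei", specs)


class TestPooledCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        b = _block({"qsm": x, "na": x, "mtr": x[::-1], "t1": x})
        res = pooled_correlation([b], ("t1", "na"))
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-6

    def test_covariance_formula_oracle(self):
        rng = np.random.default_rng(4)
        data = {c: rng.normal(size=10) for c in CONTRASTS}
        res = pooled_correlation([_block(data)], ("qsm", "mtr"))
        x, y = data["qsm"], data["mtr"]
        r = (((x - x.mean()) * (y - y.mean())).sum()
             / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert res.r == pytest.approx(r)

    def test_symmetry_and_affine_invariance(self, specs):
        subj = sample_subject(specs, CohortConfig(seed=13), 7)
        blocks = subject_blocks(subj)
        ab = pooled_correlation(blocks, ("t1", "na"))
        ba = pooled_correlation(blocks, ("na", "t1"))
        assert ab.r == pytest.approx(ba.r)
        scaled = [
            _block({**{c: b.values[c] for c in CONTRASTS},
                    "na": -3.0 * b.values["na"] + 5.0},
                   structure=b.structure, subject=b.subject_id)
            for b in blocks
        ]
        neg = pooled_correlation(scaled, ("t1", "na"))
        assert neg.r == pytest.approx(-ab.r, abs=1e-9)

    def test_zero_variance_rejected(self):
        b = _block({c: np.ones(5) if c == "qsm" else np.arange(5.0)
                    for c in CONTRASTS})
        with pytest.raises(ValueError, match="zero variance"):
            pooled_correlation([b], ("qsm", "t1"))
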