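import numpy as np
import pandas as pd
import pytest

from netplast import accessibility as acc
from netplast import synthetic


def tiny_inputs(tmp_path, matrix_rows=None, groups=None):
    bed = tmp_path / "regions.bed"
    bed.write_text(
        "chr1\t0\t5000\tr1\tgene_promoter\n"
        "chr1\t10000\t15000\tr2\ttf_promoter\n"
        "chr1\t20000\t25000\tr3\tenhancer\n"
    )
    mat = tmp_path / "matrix.tsv"
    rows = matrix_rows or ["r1\t2.0\t4.0", "r2\t1.0\t1.0", "r3\t5.0\t0.0"]
    mat.write_text("id\ts1\ts2\n" + "\n".join(rows) + "\n")
    grp = tmp_path / "groups.tsv"
    lines = groups or ["s1\tESC", "s2\tAdult"]
    grp.write_text("sample\tgroup\n" + "\n".join(lines) + "\n")
    return str(bed), str(mat), str(grp)


class TestLoadAccessibility:
    def test_loads_and_attaches_classes(self, tmp_path):
        am = acc.load_accessibility(*tiny_inputs(tmp_path))
        assert list(am.regions["cls"]) == ["gene_promoter", "tf_promoter",
                                           "enhancer"]
        assert am.groups["s1"] == "ESC"

    def test_matrix_id_absent_from_bed_rejected(self, tmp_path):
        paths = tiny_inputs(tmp_path,
                            matrix_rows=["r1\t1\t1", "rX\t1\t1", "r3\t1\t1"])
        with pytest.raises(ValueError, match="rX"):
            acc.load_accessibility(*paths)

    def test_duplicated_region_id_rejected(self, tmp_path):
        bed = tmp_path / "dup.bed"
        bed.write_text("chr1\t0\t10\tr1\tenhancer\nchr1\t20\t30\tr1\tenhancer\n")
        with pytest.raises(ValueError, match="duplicated"):
            acc.read_bed(str(bed))

    def test_sample_without_group_rejected(self, tmp_path):
        paths = tiny_inputs(tmp_path, groups=["s1\tESC"])
        with pytest.raises(ValueError, match="s2"):
            acc.load_accessibility(*paths)

    def test_negative_value_rejected(self, tmp_path):
        paths = tiny_inputs(tmp_path,
                            matrix_rows=["r1\t1\t1", "r2\t-3\t1", "r3\t1\t1"])
        with pytest.raises(ValueError, match="r2"):
            acc.load_accessibility(*paths)

    def test_invalid_interval_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t50\t50\tr1\tenhancer\n")
        with pytest.raises(ValueError, match="start"):
            acc.read_bed(str(bed))


class TestGroupMeans:
    def test_hand_computed_means(self, tmp_path):
        bed = tmp_path / "b.bed"
        bed.write_text("chr1\t0\t10\tr1\tenhancer\n")
        mat = tmp_path / "m.tsv"
        mat.write_text("id\te1\te2\ta1\ta2\ta3\nr1\t2\t4\t1\t1\t1\n")
        grp = tmp_path / "g.tsv"
        grp.write_text("sample\tgroup\ne1\tESC\ne2\tESC\n"
                       "a1\tAdult\na2\tAdult\na3\tAdult\n")
        am = acc.load_accessibility(str(bed), str(mat), str(grp))
        means = acc.group_mean_accessibility(am)
        assert means.loc["r1", "mean_ESC"] == pytest.approx(3.0)
        assert means.loc["r1", "mean_Adult"] == pytest.approx(1.0)

    def test_all_zero_region_means_zero(self, tmp_path):
        paths = tiny_inputs(tmp_path,
                            matrix_rows=["r1\t0\t0", "r2\t1\t2", "r3\t1\t1"])
        am = acc.load_accessibility(*paths)
        means = acc.group_mean_accessibility(am)
        assert means.loc["r1", "mean_ESC"] == 0.0
        assert means.loc["r1", "mean_Adult"] == 0.0

    def test_planted_shift_detected(self):
        am, _ = synthetic.make_accessibility(
            synthetic.AccessibilitySpec(regions_per_class=200,
                                        samples_per_group=6, seed=3))
        res = acc.compare_group_accessibility(am, "tf_promoter")
        assert res["median_ESC"] > res["median_Adult"]
        assert res["p_value"] < 0.01


class TestEntropy:
    def test_uniform_vector_log_r(self):
        assert acc.accessibility_entropy(np.ones(50)) == pytest.approx(np.log(50))

    def test_point_mass_zero(self):
        v = np.zeros(10)
        v[3] = 7.0
        assert acc.accessibility_entropy(v) == 0.0

    def test_hand_computed_three_regions(self):
        assert acc.accessibility_entropy([1, 1, 2]) == pytest.approx(
            1.0397, abs=1e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.gamma(2, size=100)
        h1 = acc.accessibility_entropy(v)
        h2 = acc.accessibility_entropy(v * 1e6)
        assert h1 == pytest.approx(h2)

    def test_mean_preserving_evening_increases_entropy(self):
        v = np.array([1.0, 9.0, 4.0, 4.0])
        h0 = acc.accessibility_entropy(v)
        v_evened = np.array([3.0, 7.0, 4.0, 4.0])
        assert acc.accessibility_entropy(v_evened) > h0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            acc.accessibility_entropy([5.0])
        with pytest.raises(ValueError):
            acc.accessibility_entropy([0.0, 0.0])
        with pytest.raises(ValueError):
            acc.accessibility_entropy([1.0, -1.0])

    def test_base_conversion(self):
        assert acc.accessibility_entropy([1, 1, 1, 1], base=2) == pytest.approx(2.0)


class TestCompareGroupEntropy:
    def test_identical_groups_give_p_one(self, tmp_path):
        bed = tmp_path / "b.bed"
        bed.write_text("\n".join(
            f"chr1\t{i * 10}\t{i * 10 + 5}\tr{i}\tenhancer" for i in range(4)))
        mat = tmp_path / "m.tsv"
        rows = ["\t".join([f"r{i}"] + ["1", "2", "1", "2"]) for i in range(4)]
        mat.write_text("id\te1\te2\ta1\ta2\n" + "\n".join(rows) + "\n")
        grp = tmp_path / "g.tsv"
        grp.write_text("sample\tgroup\ne1\tESC\ne2\tESC\na1\tAdult\na2\tAdult\n")
        am = acc.load_accessibility(str(bed), str(mat), str(grp))
        res = acc.compare_group_entropy(am, "enhancer")
        assert res["p_value"] == pytest.approx(1.0)

    def test_designed_gap_direction_and_significance(self):
        am, truth = synthetic.make_accessibility(
            synthetic.AccessibilitySpec(seed=1))
        res = acc.compare_group_entropy(am, "tf_promoter")
        assert res["direction"] == "ESC"
        assert res["p_value"] < 0.05

    def test_label_swap_flips_direction_not_p(self):
        am, _ = synthetic.make_accessibility(
            synthetic.AccessibilitySpec(regions_per_class=100,
                                        samples_per_group=4, seed=2))
        res = acc.compare_group_entropy(am, "enhancer")
        swapped = am.groups.map({"ESC": "Adult", "Adult": "ESC"})
        am2 = acc.AccessibilityMatrix(values=am.values, regions=am.regions,
                                      groups=swapped)
        res2 = acc.compare_group_entropy(am2, "enhancer")
        assert res["p_value"] == pytest.approx(res2["p_value"])
        assert res["direction"] != res2["direction"]

    def test_pooled_mode_reports_gap_without_test(self):
        am, _ = synthetic.make_accessibility(
            synthetic.AccessibilitySpec(regions_per_class=100,
                                        samples_per_group=4, seed=4))
        res = acc.compare_group_entropy(am, "enhancer", pooled=True)
        assert res["pooled"]
        assert np.isnan(res["p_value"])
        assert res["entropy_ESC"] > res["entropy_Adult"]
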