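import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perishell.layers import build_layers
from perishell.metrics import MetricMap
from perishell.stats import (
    LayerProfile,
    LayerTestResult,
    PerilesionalLayerModel,
    extract_profile,
    group_layer_test,
    paired_layer_test,
    proportion_percent,
    significant_extent,
    volume_metric_correlation,
)

from _oracles import paired_t_closed_form, pearson_r_formula, two_sample_t_pooled
from conftest import make_volume


def _profiles(ipsi, contra, metric="ALFF", group="g"):
    ipsi = np.atleast_2d(ipsi)
    contra = np.atleast_2d(contra)
    return [
        LayerProfile(f"s{i}", metric, a, b, group=group)
        for i, (a, b) in enumerate(zip(ipsi, contra))
    ]


@pytest.fixture(scope="module")
def layer_fixture(small_anatomy):
    layers = build_layers(small_anatomy.lesion, small_anatomy.gm, small_anatomy.hemis)
    mask = small_anatomy.gm.with_data(
        (small_anatomy.gm.as_bool() | small_anatomy.lesion.as_bool()).astype(np.uint8)
    )
    return layers, mask


class TestExtractProfile:

    def test_constant_map_gives_unit_means(self, layer_fixture):
        layers, mask = layer_fixture
        m = MetricMap(np.ones(mask.shape, dtype=np.float32), "ALFF", mask,
                      standardized=True)
        prof = extract_profile(m, layers)
        assert np.allclose(prof.ipsi_means, 1.0)
        assert np.allclose(prof.contra_means, 1.0)

    def test_layer_indexed_map_recovers_indices(self, layer_fixture):
        layers, mask = layer_fixture
        values = np.zeros(mask.shape, dtype=np.float32)
        for k, m in enumerate(layers.ipsi_layers, start=1):
            values[m] = k
        prof = extract_profile(MetricMap(values, "ALFF", mask, True), layers)
        assert np.allclose(prof.ipsi_means, np.arange(1, 11))

    def test_random_map_matches_masked_average_oracle(self, layer_fixture, rng):
        layers, mask = layer_fixture
        values = rng.random(mask.shape).astype(np.float32)
        prof = extract_profile(MetricMap(values, "ALFF", mask, True), layers)
        valid = mask.as_bool()
        for k in range(10):
            vox = values[layers.ipsi_layers[k] & valid]
            assert prof.ipsi_means[k] == pytest.approx(float(vox.mean()), abs=1e-6)

    def test_empty_layers_flagged(self, layer_fixture):
        layers, mask = layer_fixture
        tiny = mask.with_data(layers.lesion.data.copy())  # mask = lesion only
        m = MetricMap(np.ones(mask.shape, dtype=np.float32), "ALFF", tiny, True)
        prof = extract_profile(m, layers)
        assert prof.empty_layers == frozenset(range(1, 11))
        assert np.isnan(prof.ipsi_means).all()


class TestPairedTest:
    def test_identical_sides_null(self):
        vals = np.tile(np.linspace(0.8, 1.2, 10), (6, 1))
        res = paired_layer_test(_profiles(vals, vals), layer=3)
        assert res.t_stat == 0.0
        assert res.p_raw == pytest.approx(1.0)
        assert not res.significant

    def test_known_differences_match_closed_form(self):
        diffs = np.array([-0.2, -0.3, -0.25, -0.15, -0.22, -0.28, -0.2, -0.24])
        contra = np.ones((8, 10))
        ipsi = contra.copy()
        ipsi[:, 0] += diffs
        res = paired_layer_test(_profiles(ipsi, contra), layer=1)
        t_exp, p_exp = paired_t_closed_form(ipsi[:, 0], contra[:, 0])
        assert res.t_stat == pytest.approx(t_exp, abs=1e-8)
        assert res.p_raw == pytest.approx(p_exp, abs=1e-8)
        assert res.significant  # huge effect at alpha 0.005

    def test_bonferroni_threshold(self):
        vals = np.random.default_rng(0).normal(1, 0.1, size=(5, 10))
        res = paired_layer_test(_profiles(vals, vals + 0.01), layer=2,
                                family_alpha=0.05, n_comparisons=10)
        assert res.alpha_corrected == pytest.approx(0.005)

    def test_equals_one_sample_on_differences(self, rng):
        from scipy import stats as sps

        ipsi = rng.normal(1.0, 0.1, size=(9, 10))
        contra = rng.normal(1.0, 0.1, size=(9, 10))
        res = paired_layer_test(_profiles(ipsi, contra), layer=5)
        t1, p1 = sps.ttest_1samp(ipsi[:, 4] - contra[:, 4], 0.0)
        assert res.t_stat == pytest.approx(float(t1), abs=1e-10)
        assert res.p_raw == pytest.approx(float(p1), abs=1e-10)

    def test_swap_flips_sign_keeps_p(self, rng):
        ipsi = rng.normal(1.0, 0.1, size=(8, 10))
        contra = rng.normal(1.0, 0.1, size=(8, 10))
        fwd = paired_layer_test(_profiles(ipsi, contra), layer=1)
        rev = paired_layer_test(_profiles(contra, ipsi), layer=1)
        assert fwd.t_stat == pytest.approx(-rev.t_stat, abs=1e-10)
        assert fwd.p_raw == pytest.approx(rev.p_raw, abs=1e-12)

    def test_empty_layer_subjects_dropped_pairwise(self, rng):
        ipsi = rng.normal(1.0, 0.05, size=(6, 10))
        contra = rng.normal(1.0, 0.05, size=(6, 10))
        ipsi[0, 0] = np.nan  # subject 0 empty at layer 1
        res = paired_layer_test(_profiles(ipsi, contra), layer=1)
        assert res.n_subjects == 5
        res5 = paired_layer_test(_profiles(ipsi[1:], contra[1:]), layer=1)
        assert res.t_stat == pytest.approx(res5.t_stat, abs=1e-12)

    def test_too_few_subjects(self):
        res = paired_layer_test(_profiles(np.ones((2, 10)), np.ones((2, 10))), 1)
        assert not res.significant and res.note == "n < 3"


class TestGroupTest:
    def test_identical_groups_null(self):
        vals = np.tile(np.linspace(0.9, 1.1, 10), (5, 1))
        res = group_layer_test(_profiles(vals, vals), _profiles(vals, vals), layer=4)
        assert res.t_stat == 0.0 and not res.significant

    def test_separated_groups_significant(self):
        a = np.ones((5, 10))
        b = np.ones((5, 10)) + 0.5
        res = group_layer_test(_profiles(a, a), _profiles(b, b), layer=1)
        assert res.significant and res.p_raw == pytest.approx(0.0, abs=1e-12)

    def test_random_groups_match_pooled_closed_form(self, rng):
        a = rng.normal(1.0, 0.1, size=(7, 10))
        b = rng.normal(0.9, 0.15, size=(9, 10))
        res = group_layer_test(_profiles(a, a), _profiles(b, b), layer=6)
        t_exp, p_exp = two_sample_t_pooled(a[:, 5], b[:, 5])
        assert res.t_stat == pytest.approx(t_exp, abs=1e-10)
        assert res.p_raw == pytest.approx(p_exp, abs=1e-10)

    def test_welch_differs_under_unequal_variance(self, rng):
        a = rng.normal(1.0, 0.01, size=(6, 10))
        b = rng.normal(1.0, 0.5, size=(20, 10))
        student = group_layer_test(_profiles(a, a), _profiles(b, b), 1)
        welch = group_layer_test(_profiles(a, a), _profiles(b, b), 1, welch=True)
        assert student.t_stat != pytest.approx(welch.t_stat)


class TestCorrelation:
    def test_perfect_positive(self, rng):
        vols = rng.normal(3, 0.5, size=6)
        profs = _profiles(np.tile(vols[:, None], (1, 10)), np.ones((6, 10)))
        r, p = volume_metric_correlation(profs, vols, layer=1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_negative(self, rng):
        vols = rng.normal(3, 0.5, size=6)
        profs = _profiles(np.tile(-vols[:, None], (1, 10)), np.ones((6, 10)))
        r, _ = volume_metric_correlation(profs, vols, layer=2)
        assert r == pytest.approx(-1.0)

    def test_random_matches_formula(self, rng):
        vols = rng.normal(3, 0.5, size=12)
        means = rng.normal(1, 0.1, size=(12, 10))
        profs = _profiles(means, means)
        r, _ = volume_metric_correlation(profs, vols, layer=7)
        assert r == pytest.approx(pearson_r_formula(vols, means[:, 6]), abs=1e-10)

    def test_constant_input_undefined(self):
        profs = _profiles(np.ones((5, 10)), np.ones((5, 10)))
        r, p = volume_metric_correlation(profs, np.ones(5), layer=1)
        assert np.isnan(r) and np.isnan(p)


def _pattern(bools):
    return [
        LayerTestResult(k + 1, 0.0, 0.0, 0.005, sig, 10)
        for k, sig in enumerate(bools)
    ]


class TestSignificantExtent:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ((1, 1, 1, 1, 1, 1, 0, 0, 0, 0), 6),
            ((1, 1, 0, 0, 0, 0, 0, 0, 0, 0), 2),
            ((0, 0, 0, 0, 0, 0, 0, 0, 0, 0), 0),
            ((1, 0, 1, 1, 0, 0, 0, 0, 0, 0), 1),  # gap truncates the run
            ((1,) * 10, 10),
        ],
    )
    def test_contiguous_run(self, pattern, expected):
        assert significant_extent(_pattern(pattern)) == expected

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.booleans(), min_size=10, max_size=10))
    def test_matches_naive_scan(self, bools):
        expected = 0
        for b in bools:
            if not b:
                break
            expected += 1
        assert significant_extent(_pattern(bools)) == expected


class TestModel:
    def _cohort_profiles(self, rng):
        profs = []
        for g, shift in (("IIa", np.r_[[-0.3] * 6, [0.0] * 4]),
                         ("IIb", np.r_[[-0.3] * 2, [0.0] * 8])):
            for i in range(10):
                contra = rng.normal(1.0, 0.05, 10)
                ipsi = contra + shift + rng.normal(0, 0.05, 10)
                profs.append(LayerProfile(f"{g}-{i}", "ALFF", ipsi, contra, group=g))
        return profs

    def test_fit_recovers_group_extents(self, rng):
        model = PerilesionalLayerModel(self._cohort_profiles(rng))
        res = model.fit()
        assert res.extent("ALFF", "IIa") == 6
        assert res.extent("ALFF", "IIb") == 2
        summary = res.summary()
        assert "layers 1-6" in summary and "layers 1-2" in summary

    def test_between_group_table_present(self, rng):
        res = PerilesionalLayerModel(self._cohort_profiles(rng)).fit()
        bf = res.between_frame()
        assert set(bf["layer"]) == set(range(1, 11))
        # groups differ at layers 3-6 (IIa deficit, IIb none)
        sig = bf.set_index("layer")["significant"]
        assert sig.loc[4] and sig.loc[5]

    def test_from_dataframe_round_trip(self, rng):
        profs = self._cohort_profiles(rng)
        rows = []
        for p in profs:
            for k in range(10):
                rows.append(dict(subject=p.subject_id, group=p.group, metric=p.metric,
                                 layer=k + 1, ipsi_mean=p.ipsi_means[k],
                                 contra_mean=p.contra_means[k]))
        model = PerilesionalLayerModel.from_dataframe(pd.DataFrame(rows))
        res = model.fit()
        assert res.extent("ALFF", "IIa") == 6

    def test_paired_frame_is_tidy(self, rng):
        res = PerilesionalLayerModel(self._cohort_profiles(rng)).fit()
        df = res.paired_frame()
        assert list(df.columns) == [
            "metric", "group", "layer", "n", "t", "p", "alpha_corrected", "significant"
        ]
        assert len(df) == 20  # 1 metric x 2 groups x 10 layers

    def test_volume_correlation_battery(self, rng):
        profs = self._cohort_profiles(rng)
        vols = {p.subject_id: float(rng.normal(3, 0.4)) for p in profs}
        res = PerilesionalLayerModel(profs, log_volumes=vols).fit()
        assert ("ALFF", "IIa", 1) in res.correlations
        r, p = res.correlations[("ALFF", "IIa", 1)]
        assert -1 <= r <= 1 and 0 <= p <= 1


class TestPlotting:
    def test_profile_plot_smoke(self, rng):
        import matplotlib

        matplotlib.use("Agg")
        contra = rng.normal(1.0, 0.05, size=(6, 10))
        ipsi = contra - 0.2
        profs = _profiles(ipsi, contra)
        res = PerilesionalLayerModel(profs).fit()
        ax = res.plot_profiles("ALFF", "g")
        assert ax.get_xlabel().startswith("perilesional")
        labels = [t.get_text() for t in ax.get_legend().get_texts()]
        assert any("ipsi" in l for l in labels)


class TestCounts:
    def test_cohort_percentages(self):
        assert proportion_percent(30, 39) == 76.9
        assert proportion_percent(26, 30) == 86.7
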