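"""Point estimates for the 16 accuracy measures, checked against printed
study values and an independent brute-force formula oracle."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxmetrics import (
    EmptyTableError,
    UndefinedMeasureError,
    build_panel,
    diagnostic_odds_ratio,
    f_score,
    kappa,
    likelihood_ratio,
    likelihood_ratios,
    proportion_measure,
    table_from_counts,
    youden_index,
)
from dxmetrics.measures import PANEL_ORDER
from dxmetrics.report import round_half_up

from conftest import CAD_COUNTS, brute_force_measure

PROPORTION_KEYS = [
    "sensitivity", "specificity", "ppv", "npv", "fpr",
    "fnr", "for", "fdr", "accuracy", "prevalence",
]


class TestProportionMeasures:
    def test_sensitivity_published(self, mdbs_table):
        num, den, p = proportion_measure(mdbs_table, "sensitivity")
        assert (num, den) == (213, 236)
        assert round_half_up(100 * float(p), 1) == 90.3

    def test_accuracy_published_cross_platform(self):
        table = table_from_counts(219, 343, 13, 169)
        num, den, p = proportion_measure(table, "accuracy")
        assert (num, den) == (388, 744)
        assert round_half_up(100 * float(p), 1) == 52.2

    def test_zero_numerator_is_zero_not_undefined(self):
        _, _, p = proportion_measure(table_from_counts(0, 0, 5, 5), "sensitivity")
        assert p == 0

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(UndefinedMeasureError):
            proportion_measure(table_from_counts(0, 5, 0, 5), "sensitivity")

    def test_complement_identities_exact(self):
        """FPR+spec, FNR+sens, FOR+NPV, FDR+PPV all equal 1 in exact arithmetic."""
        for counts in itertools.product(range(4), repeat=4):
            t = table_from_counts(*counts)
            for pair in (("fpr", "specificity"), ("fnr", "sensitivity"),
                         ("for", "npv"), ("fdr", "ppv")):
                try:
                    p1 = proportion_measure(t, pair[0])[2]
                    p2 = proportion_measure(t, pair[1])[2]
                except UndefinedMeasureError:
                    continue
                assert p1 + p2 == 1


class TestRatioMeasures:
    def test_published_likelihood_ratios(self, mdbs_table):
        lr_pos, lr_neg = likelihood_ratios(mdbs_table)
        assert round_half_up(lr_pos, 1) == 17.6
        assert lr_neg == pytest.approx((23 / 236) / (480 / 506), abs=1e-12)
        assert round_half_up(lr_neg, 1) == 0.1

    def test_uninformative_test_has_unit_ratios(self):
        lr_pos, lr_neg = likelihood_ratios(table_from_counts(5, 5, 5, 5))
        assert lr_pos == lr_neg == 1.0

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((213, 26, 23, 480), 171.0),
            ((52, 1, 2, 20), 520.0),
            ((51, 15, 3, 6), 6.8),  # printed table value, not the prose's 6.4
            ((1, 1, 1, 1), 1.0),
        ],
    )
    def test_diagnostic_odds_ratio(self, counts, expected):
        assert round_half_up(diagnostic_odds_ratio(table_from_counts(*counts)), 1) == expected

    def test_dor_equals_ratio_of_likelihood_ratios(self):
        for counts in [(213, 26, 23, 480), (52, 1, 2, 20), (7, 3, 2, 9)]:
            t = table_from_counts(*counts)
            lr_pos, lr_neg = likelihood_ratios(t)
            assert diagnostic_odds_ratio(t) == pytest.approx(lr_pos / lr_neg, rel=1e-12)


class TestIndexMeasures:
    def test_kappa_published(self, mdbs_table):
        po, pe, k = kappa(mdbs_table)
        assert po == pytest.approx(693 / 742, abs=1e-12)
        assert pe == pytest.approx((236 * 239 + 506 * 503) / 742**2, abs=1e-12)
        assert k == pytest.approx(0.8483, abs=5e-5)

    def test_kappa_extremes(self):
        assert kappa(table_from_counts(5, 0, 0, 5))[2] == 1.0
        assert kappa(table_from_counts(1, 1, 1, 1))[2] == 0.0

    def test_youden_published_and_extremes(self, mdbs_table):
        assert youden_index(mdbs_table) == pytest.approx(0.8512, abs=5e-5)
        assert youden_index(table_from_counts(5, 0, 0, 5)) == 1.0
        assert youden_index(table_from_counts(5, 5, 5, 5)) == 0.0

    def test_f_score_published(self, mdbs_table):
        assert f_score(table_from_counts(52, 1, 2, 20)) == pytest.approx(104 / 107)
        assert f_score(mdbs_table) == pytest.approx(426 / 475)
        assert f_score(table_from_counts(0, 3, 4, 2)) == 0.0

    @given(counts=st.tuples(*[st.integers(0, 500)] * 4))
    @settings(max_examples=1000, deadline=None)
    def test_f_score_is_harmonic_mean_of_ppv_and_sensitivity(self, counts):
        a, b, c, d = counts
        t = table_from_counts(a, b, c, d)
        if 2 * a + b + c == 0 or a + b == 0 or a + c == 0:
            return
        ppv = a / (a + b)
        sens = a / (a + c)
        if ppv + sens == 0:
            return
        assert f_score(t) == pytest.approx(2 * ppv * sens / (ppv + sens), abs=1e-12)


def test_every_measure_matches_brute_force_oracle_exhaustively():
    """All tables with cells in {0..6}: each defined measure equals a direct
    independent evaluation of its formula; undefined measures stay undefined."""
    keys = PROPORTION_KEYS + ["kappa", "youden", "fscore", "lr_pos", "lr_neg", "dor"]
    for counts in itertools.product(range(7), repeat=4):
        t = table_from_counts(*counts)
        for key in keys:
            expected = brute_force_measure(*counts, which=key)
            try:
                if key in PROPORTION_KEYS:
                    got = float(proportion_measure(t, key)[2])
                elif key == "kappa":
                    got = kappa(t)[2]
                elif key == "youden":
                    got = youden_index(t)
                elif key == "fscore":
                    got = f_score(t)
                elif key in ("lr_pos", "lr_neg"):
                    got = likelihood_ratio(t, key, zero_cell_correction=False)
                else:
                    got = diagnostic_odds_ratio(t, zero_cell_correction=False)
            except UndefinedMeasureError:
                got = None
            if expected is None:
                assert got is None, (counts, key, got)
            else:
                assert got is not None and got == pytest.approx(expected, abs=1e-12), (
                    counts,
                    key,
                    expected,
                )


class TestBuildPanel:
    def test_panel_order_and_published_rounding(self, mdbs_table, default_config):
        panel = build_panel(mdbs_table, default_config)
        assert [e.name for e in panel.estimates] == [k for k, _, _ in PANEL_ORDER]
        expected_points = {
            "sensitivity": 90.3, "specificity": 94.9, "ppv": 89.1, "npv": 95.4,
            "fpr": 5.1, "fnr": 9.7, "for": 4.6, "fdr": 10.9,
            "accuracy": 93.4, "prevalence": 31.8,
        }
        for key, want in expected_points.items():
            est = panel[key]
            assert round_half_up(100 * est.point, 1) == want

    def test_symmetric_table_panel(self, default_config):
        panel = build_panel(table_from_counts(1, 1, 1, 1), default_config)
        for key in ("sensitivity", "specificity", "ppv", "npv"):
            assert panel[key].point == 0.5

    def test_empty_table_rejected(self, default_config):
        with pytest.raises((EmptyTableError, Exception)):
            build_panel(table_from_counts(0, 0, 0, 0), default_config)

    def test_undefined_measures_render_as_missing(self, default_config):
        # no truth-negatives: specificity/FPR undefined, not zero
        panel = build_panel(table_from_counts(5, 0, 5, 0), default_config)
        assert panel["specificity"].point is None
        assert panel["sensitivity"].point == 0.5

    def test_accuracy_identity(self, default_config):
        """accuracy = prev * sens + (1 - prev) * spec for any complete table."""
        for counts in [(213, 26, 23, 480), (52, 1, 2, 20), (3, 4, 5, 6)]:
            panel = build_panel(table_from_counts(*counts), default_config)
            prev = panel["prevalence"].point
            combo = prev * panel["sensitivity"].point + (1 - prev) * panel["specificity"].point
            assert panel["accuracy"].point == pytest.approx(combo, abs=1e-12)


@pytest.mark.parametrize("name, counts", list(CAD_COUNTS.items()))
def test_cad_published_sens_spec_dor(name, counts, default_config):
    published = {
        "bagging": (92.6, 81.0, 53.1),
        "knn": (94.4, 28.6, 6.8),
        "svm": (96.3, 95.2, 520.0),
        "rf": (96.3, 81.0, 110.5),
        "lr": (94.4, 81.0, 72.3),
    }
    panel = build_panel(table_from_counts(*counts), default_config)
    sens, spec, dor = published[name]
    assert round_half_up(100 * panel["sensitivity"].point, 1) == sens
    assert round_half_up(100 * panel["specificity"].point, 1) == spec
    assert round_half_up(panel["dor"].point, 1) == dor
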