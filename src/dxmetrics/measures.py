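"""Point estimates for the 16 diagnostic accuracy measures.

All internal computation is on proportions; percent-scale measures are
multiplied by 100 only at reporting time. Measures whose denominator is
empty raise :class:`~dxmetrics.errors.UndefinedMeasureError` and are rendered
with the configured missing label, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal

from .contingency import AnalysisConfig, ConfusionTable
from .errors import EmptyTableError, UndefinedMeasureError
from . import intervals

Scale = Literal["percent", "ratio", "index"]

#: (numerator cell expression, denominator margin) for each proportion measure.
_PROPORTION_DEFS = {
    "sensitivity": ("a", "m1"),
    "specificity": ("d", "m2"),
    "ppv": ("a", "n1"),
    "npv": ("d", "n2"),
    "fpr": ("b", "m2"),
    "fnr": ("c", "m1"),
    "for": ("c", "n2"),
    "fdr": ("b", "n1"),
    "accuracy": ("a+d", "n"),
    "prevalence": ("m1", "n"),
}

#: Display order and labels of the full measure panel.
PANEL_ORDER = [
    ("sensitivity", "Sensitivity (%)", "percent"),
    ("specificity", "Specificity (%)", "percent"),
    ("ppv", "Positive Predictive Value (PPV) (%)", "percent"),
    ("npv", "Negative Predictive Value (NPV) (%)", "percent"),
    ("fpr", "Upward Misclassification (%)", "percent"),
    ("fnr", "Downward Misclassification (%)", "percent"),
    ("for", "False Omission Rate (FOR) (%)", "percent"),
    ("fdr", "False Discovery Rate (FDR) (%)", "percent"),
    ("lr_pos", "Positive Likelihood Ratio (LR+)", "ratio"),
    ("lr_neg", "Negative Likelihood Ratio (LR-)", "ratio"),
    ("accuracy", "Diagnostic Accuracy (%)", "percent"),
    ("prevalence", "Disease Prevalence (%)", "percent"),
    ("dor", "Diagnostic Odds Ratio (DOR)", "ratio"),
    ("kappa", "Kappa Agreement", "index"),
    ("youden", "Youden's Index", "index"),
    ("fscore", "F-score", "index"),
]

MEASURE_LABELS = {key: label for key, label, _ in PANEL_ORDER}


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its confidence bounds.

    ``lower``/``upper`` are None when the interval (or the whole measure) is
    not estimable. Percent-scale values are stored as proportions; the
    reporting layer rescales to 0-100.
    """

    name: str
    point: float | None
    lower: float | None
    upper: float | None
    scale: Scale
    method: str
    alpha: float

    @property
    def defined(self) -> bool:
        return self.point is not None


@dataclass(frozen=True)
class DamPanel:
    """The 16 measure estimates for one test against one reference."""

    test_name: str
    reference_name: str
    table: ConfusionTable
    estimates: tuple[Estimate, ...]

    def __getitem__(self, name: str) -> Estimate:
        for est in self.estimates:
            if est.name == name:
                return est
        raise KeyError(name)


def _cell_sum(table, expr: str) -> float:
    return sum(getattr(table, part) for part in expr.split("+"))


def proportion_measure(
    table: ConfusionTable, which: str
) -> tuple[int, int, Fraction]:
    """Exact numerator, denominator and proportion for a simple rate measure.

    The proportion is returned as a :class:`fractions.Fraction` so the
    complement identities (FPR = 1 - specificity, etc.) hold exactly.
    """
    try:
        num_expr, den_expr = _PROPORTION_DEFS[which]
    except KeyError:
        raise UndefinedMeasureError(f"unknown proportion measure {which!r}") from None
    num = int(_cell_sum(table, num_expr))
    den = int(_cell_sum(table, den_expr))
    if den == 0:
        raise UndefinedMeasureError(f"{which} undefined: denominator {den_expr} is 0")
    return num, den, Fraction(num, den)


def likelihood_ratio(
    table: ConfusionTable,
    kind: Literal["lr_pos", "lr_neg"],
    zero_cell_correction: bool = True,
) -> float:
    """One likelihood ratio: LR+ = sens / (1 - spec) or LR- = (1 - sens) / spec.

    A zero cell anywhere triggers the Haldane-Anscombe correction when
    enabled; with correction off, the ratio is undefined exactly when its
    own denominator vanishes (b = 0 for LR+, d = 0 for LR-, or an empty
    truth margin).
    """
    required = ("b",) if kind == "lr_pos" else ("d",)
    work = intervals.ratio_work_table(table, required, zero_cell_correction)
    if work.m1 == 0 or work.m2 == 0:
        raise UndefinedMeasureError(f"{kind} undefined: empty truth margin")
    if kind == "lr_pos":
        return (work.a / work.m1) / (work.b / work.m2)
    return (work.c / work.m1) / (work.d / work.m2)


def likelihood_ratios(
    table: ConfusionTable, zero_cell_correction: bool = True
) -> tuple[float, float]:
    """The (LR+, LR-) pair; undefined if either component is."""
    return (
        likelihood_ratio(table, "lr_pos", zero_cell_correction),
        likelihood_ratio(table, "lr_neg", zero_cell_correction),
    )


def diagnostic_odds_ratio(table: ConfusionTable, zero_cell_correction: bool = True) -> float:
    """DOR = (a*d) / (b*c), equal to LR+ / LR-."""
    work = intervals.ratio_work_table(table, ("b", "c"), zero_cell_correction)
    return (work.a * work.d) / (work.b * work.c)


def kappa(table: ConfusionTable) -> tuple[float, float, float]:
    """Cohen's kappa with its observed (po) and chance (pe) agreement."""
    n = table.n
    if n == 0:
        raise UndefinedMeasureError("kappa undefined on an empty table")
    po = (table.a + table.d) / n
    pe = (table.m1 * table.n1 + table.m2 * table.n2) / (n * n)
    if pe == 1.0:
        raise UndefinedMeasureError("kappa undefined: degenerate margins (pe = 1)")
    return po, pe, (po - pe) / (1.0 - pe)


def youden_index(table: ConfusionTable) -> float:
    """Youden's J = sensitivity + specificity - 1."""
    _, _, sens = proportion_measure(table, "sensitivity")
    _, _, spec = proportion_measure(table, "specificity")
    return float(sens + spec - 1)


def f_score(table: ConfusionTable) -> float:
    """F-score = 2a / (2a + b + c), the harmonic mean of PPV and sensitivity."""
    denom = 2 * table.a + table.b + table.c
    if denom == 0:
        raise UndefinedMeasureError("F-score undefined: 2a+b+c = 0")
    return 2 * table.a / denom


def _estimate(name, scale, method, alpha, compute):
    """Run one measure+interval computation, mapping undefined to a blank Estimate."""
    try:
        point, (lower, upper) = compute()
    except UndefinedMeasureError:
        return Estimate(name, None, None, None, scale, method, alpha)
    return Estimate(name, float(point), lower, upper, scale, method, alpha)


def build_panel(
    table: ConfusionTable,
    config: AnalysisConfig,
    test_name: str = "test",
    reference_name: str = "reference",
) -> DamPanel:
    """Compute all 16 measures with confidence intervals in display order."""
    if table.n == 0:
        raise EmptyTableError("cannot build a measure panel from an empty table")
    alpha = config.alpha
    corr = config.zero_cell_correction
    ests: list[Estimate] = []
    for key, _, scale in PANEL_ORDER:
        if key in _PROPORTION_DEFS:

            def compute(key=key):
                x, m, p = proportion_measure(table, key)
                return p, intervals.proportion_interval(x, m, config)

            ests.append(_estimate(key, scale, config.varmethod, alpha, compute))
        elif key in ("lr_pos", "lr_neg"):

            def compute(key=key):
                point = likelihood_ratio(table, key, corr)
                return point, intervals.log_ratio_interval(key, table, alpha, corr)

            ests.append(_estimate(key, scale, "log", alpha, compute))
        elif key == "dor":
            ests.append(
                _estimate(
                    key,
                    scale,
                    "log",
                    alpha,
                    lambda: (
                        diagnostic_odds_ratio(table, corr),
                        intervals.log_ratio_interval("dor", table, alpha, corr),
                    ),
                )
            )
        elif key == "kappa":
            ests.append(
                _estimate(
                    key,
                    scale,
                    "asymptotic",
                    alpha,
                    lambda: (kappa(table)[2], intervals.kappa_interval(table, alpha)),
                )
            )
        elif key == "youden":
            ests.append(
                _estimate(
                    key,
                    scale,
                    "wald-variance",
                    alpha,
                    lambda: (youden_index(table), intervals.youden_interval(table, alpha)),
                )
            )
        elif key == "fscore":
            ests.append(
                _estimate(
                    key,
                    scale,
                    config.varmethod,
                    alpha,
                    lambda: (
                        f_score(table),
                        intervals.fscore_interval(table, alpha, config.varmethod),
                    ),
                )
            )
    return DamPanel(
        test_name=test_name,
        reference_name=reference_name,
        table=table,
        estimates=tuple(ests),
    )
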