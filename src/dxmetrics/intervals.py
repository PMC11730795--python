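"""Confidence-interval constructions for diagnostic accuracy measures.

Three binomial interval methods are provided for proportion-scale measures:

* Wald ("normal"): ``p +/- z * sqrt(p(1-p)/n)``, the central-limit normal
  approximation. Simple but can overshoot [0, 1] and collapses to zero width
  at p = 0 or 1; bounds are reported unclipped by default.
* Wilson ("wilson"): the score interval, asymmetric, always inside [0, 1],
  safe for small n and skewed p.
* Clopper-Pearson ("exact"): inverts the binomial tails via beta quantiles,
  ``lower = B(alpha/2; x, n-x+1)``, ``upper = B(1-alpha/2; x+1, n-x)``, with
  closed forms at x = 0 and x = n. Conservative (coverage >= nominal).

Ratio measures use log-scale normal intervals: the Simel standard errors for
the likelihood ratios and the Woolf standard error for the diagnostic odds
ratio. Cohen's kappa uses the asymptotic standard error
``sqrt(po(1-po) / (n (1-pe)^2))``. Youden's index gets a Wald interval from
the summed sensitivity/specificity variances, and the F-score a binomial
interval on (2a, 2a+b+c).
"""

from __future__ import annotations

import math
from typing import Literal

from scipy import stats

from .contingency import AnalysisConfig, ConfusionTable
from .errors import UndefinedMeasureError

Method = Literal["normal", "wilson", "exact"]


def z_value(alpha: float) -> float:
    """Standard normal quantile at 1 - alpha/2."""
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


def _check_xn(x: int, n: int) -> None:
    if n < 1:
        raise UndefinedMeasureError(f"interval undefined for n={n}")
    if not 0 <= x <= n:
        raise UndefinedMeasureError(f"need 0 <= x <= n, got x={x}, n={n}")


def wald_interval(
    x: int, n: int, alpha: float = 0.05, clip: bool = False
) -> tuple[float, float]:
    """Normal-approximation (Wald) interval for a binomial proportion.

    Bounds may fall outside [0, 1] unless ``clip`` is set, and the interval
    degenerates to zero width at x = 0 or x = n; both are documented flaws of
    the method rather than bugs.
    """
    _check_xn(x, n)
    p = x / n
    half = z_value(alpha) * math.sqrt(p * (1.0 - p) / n)
    lower, upper = p - half, p + half
    if clip:
        lower, upper = max(0.0, lower), min(1.0, upper)
    return lower, upper


def wilson_interval(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval; asymmetric and always within [0, 1]."""
    _check_xn(x, n)
    p = x / n
    z = z_value(alpha)
    z2 = z * z
    denom = 1.0 + z2 / n
    centre = p + z2 / (2.0 * n)
    half = z * math.sqrt(p * (1.0 - p) / n + z2 / (4.0 * n * n))
    # clamp away floating-point spill just outside [0, 1] at the endpoints
    return max(0.0, (centre - half) / denom), min(1.0, (centre + half) / denom)


def clopper_pearson_interval(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) interval from beta quantiles.

    The edge cases use the closed forms (0, 1-(alpha/2)^(1/n)) at x = 0 and
    ((alpha/2)^(1/n), 1) at x = n.
    """
    _check_xn(x, n)
    if x == 0:
        return 0.0, 1.0 - (alpha / 2.0) ** (1.0 / n)
    if x == n:
        return (alpha / 2.0) ** (1.0 / n), 1.0
    lower = float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lower, upper


def binomial_interval(
    x: int, n: int, alpha: float = 0.05, method: Method = "normal", clip_wald: bool = False
) -> tuple[float, float]:
    """Dispatch to the selected binomial interval method."""
    if method == "normal":
        return wald_interval(x, n, alpha, clip=clip_wald)
    if method == "wilson":
        return wilson_interval(x, n, alpha)
    if method == "exact":
        return clopper_pearson_interval(x, n, alpha)
    raise UndefinedMeasureError(f"unknown interval method {method!r}")


def _ratio_cells(table, kind: str) -> tuple[float, float]:
    """Point estimate and log-scale SE for a ratio measure on (possibly
    continuity-corrected) cells."""
    a, b, c, d = table.a, table.b, table.c, table.d
    m1, m2 = table.m1, table.m2
    if kind == "lr_pos":
        if a == 0 and b == 0:
            raise UndefinedMeasureError("LR+ undefined: no information in either class")
        point = (a / m1) / (b / m2)
        se = math.sqrt(1.0 / a - 1.0 / m1 + 1.0 / b - 1.0 / m2)
    elif kind == "lr_neg":
        point = (c / m1) / (d / m2)
        se = math.sqrt(1.0 / c - 1.0 / m1 + 1.0 / d - 1.0 / m2)
    elif kind == "dor":
        point = (a * d) / (b * c)
        se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    else:
        raise UndefinedMeasureError(f"unknown ratio kind {kind!r}")
    return point, se


#: Cells whose count appears in the log-scale SE of each ratio measure.
RATIO_SE_CELLS = {"lr_pos": ("a", "b"), "lr_neg": ("c", "d"), "dor": ("a", "b", "c", "d")}


def ratio_work_table(
    table: ConfusionTable, required_cells: tuple[str, ...], zero_cell_correction: bool
):
    """Table to compute a ratio quantity on.

    Any empty cell triggers the Haldane-Anscombe correction (0.5 added to
    every cell) when enabled, keeping the point estimates and their log-method
    intervals mutually consistent. With correction disabled the raw table is
    returned, unless one of ``required_cells`` — the counts this particular
    quantity cannot be computed without — is empty.
    """
    if table.has_zero_cell():
        if zero_cell_correction:
            return table.corrected()
        if any(getattr(table, cell) == 0 for cell in required_cells):
            raise UndefinedMeasureError("ratio undefined with a zero cell")
    return table


def log_ratio_interval(
    kind: Literal["lr_pos", "lr_neg", "dor"],
    table: ConfusionTable,
    alpha: float = 0.05,
    zero_cell_correction: bool = True,
) -> tuple[float, float]:
    """Log-method interval exp(ln R +/- z * se) for LR+, LR- or DOR.

    Tables with an empty cell use the Haldane-Anscombe correction when
    enabled; otherwise the interval is undefined whenever a cell entering
    the standard error is empty.
    """
    work = ratio_work_table(table, RATIO_SE_CELLS[kind], zero_cell_correction)
    point, se = _ratio_cells(work, kind)
    if point <= 0.0:
        raise UndefinedMeasureError(f"{kind} interval undefined at ratio {point}")
    z = z_value(alpha)
    return point * math.exp(-z * se), point * math.exp(z * se)


def kappa_interval(table: ConfusionTable, alpha: float = 0.05) -> tuple[float, float]:
    """Asymptotic interval for Cohen's kappa, truncated to [-1, 1]."""
    n = table.n
    if n == 0:
        raise UndefinedMeasureError("kappa undefined on an empty table")
    po = (table.a + table.d) / n
    pe = (table.m1 * table.n1 + table.m2 * table.n2) / (n * n)
    if pe == 1.0:
        raise UndefinedMeasureError("kappa undefined: degenerate margins (pe = 1)")
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    half = z_value(alpha) * se
    return max(-1.0, kappa - half), min(1.0, kappa + half)


def youden_interval(table: ConfusionTable, alpha: float = 0.05) -> tuple[float, float]:
    """Wald-variance interval for Youden's J, truncated to [-1, 1].

    Var(J) is approximated by Var(sens) + Var(spec) since the two proportions
    come from independent binomial margins.
    """
    m1, m2 = table.m1, table.m2
    if m1 == 0 or m2 == 0:
        raise UndefinedMeasureError("Youden interval undefined: empty margin")
    sens = table.a / m1
    spec = table.d / m2
    j = sens + spec - 1.0
    var = sens * (1.0 - sens) / m1 + spec * (1.0 - spec) / m2
    half = z_value(alpha) * math.sqrt(var)
    return max(-1.0, j - half), min(1.0, j + half)


def fscore_interval(
    table: ConfusionTable, alpha: float = 0.05, method: Method = "normal"
) -> tuple[float, float]:
    """Binomial interval applied to the F-score as 2a successes in 2a+b+c trials."""
    x, n = 2 * table.a, 2 * table.a + table.b + table.c
    if n == 0:
        raise UndefinedMeasureError("F-score interval undefined: 2a+b+c = 0")
    return binomial_interval(x, n, alpha, method)


def derived_index_interval(
    kind: Literal["youden", "fscore"],
    table: ConfusionTable,
    alpha: float = 0.05,
    method: Method = "normal",
) -> tuple[float, float]:
    """Interval for the composite indices (Youden's J, F-score)."""
    if kind == "youden":
        return youden_interval(table, alpha)
    if kind == "fscore":
        return fscore_interval(table, alpha, method)
    raise UndefinedMeasureError(f"unknown derived index {kind!r}")


def proportion_interval(
    x: int, n: int, config: AnalysisConfig
) -> tuple[float, float]:
    """Binomial interval using the method and alpha of an AnalysisConfig."""
    return binomial_interval(
        x, n, alpha=config.alpha, method=config.varmethod, clip_wald=config.clip_wald
    )
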