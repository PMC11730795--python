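"""Subject-level data handling and 2x2 contingency-table construction.

A diagnostic-accuracy analysis starts from subject-level records holding one
reference ("truth" / gold standard) variable and one or more candidate test
variables, all numeric. Each variable is dichotomized at a cutoff (value >=
cutoff -> positive by default) and every test is cross-classified against the
reference in a 2x2 table with cells

    a = true positives   b = false positives
    c = false negatives  d = true negatives

and margins n1 = a+b (test positive), n2 = c+d (test negative),
m1 = a+c (truth positive), m2 = b+d (truth negative), n = a+b+c+d.
"""

from __future__ import annotations

import math
import operator
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyTableError, InputError

Direction = Literal["ge", "le"]

#: Comparison operators accepted in a row-condition string.
_CONDITION_OPS: dict[str, Callable] = {
    "==": operator.eq,
    "!=": operator.ne,
    "<=": operator.le,
    ">=": operator.ge,
    "<": operator.lt,
    ">": operator.gt,
}

_CLAUSE_RE = re.compile(
    r"^\s*([A-Za-z_][A-Za-z0-9_]*)\s*(==|!=|<=|>=|<|>)\s*([-+0-9.eE]+)\s*$"
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Run parameters for one diagnostic-accuracy analysis.

    Parameters
    ----------
    truth_cut, test_cut
        Dichotomization cutoffs for the reference and test variables.
        With the default ``ge`` direction, ``value >= cutoff`` is classified
        positive (diseased); already 0/1-coded variables should use 0.5.
    domain_value
        If given, restrict the analysis to rows whose domain column equals
        this value; requires ``SubjectTable.domain_column`` to be set.
    condition
        Optional row filter: either a callable ``row -> bool`` or a string of
        simple comparisons joined by ``and`` (e.g. ``"age >= 18 and site == 2"``).
    alpha
        Significance level for all confidence intervals (default 0.05).
    varmethod
        Binomial CI construction for proportion-scale measures:
        ``normal`` (Wald, default), ``wilson`` (score) or ``exact``
        (Clopper-Pearson).
    decimal_points
        Decimal places used at rendering time (default 1).
    miss_value_label
        Label rendered for measures that are not estimable, and recognised as
        a missing marker on input (default ".").
    truth_direction, test_direction
        ``ge`` (default) classifies value >= cutoff as positive; ``le``
        reverses the comparison for tests where low values indicate disease.
    zero_cell_correction
        When True (default), ratio measures (LR+, LR-, DOR) on tables with an
        empty cell are computed after adding 0.5 to every cell
        (Haldane-Anscombe); when False such measures are reported undefined.
    clip_wald
        When True, Wald interval bounds are clipped into [0, 1]; off by
        default since overshoot is a documented property of the method.
    """

    truth_cut: float
    test_cut: float
    domain_value: float | None = None
    condition: str | Callable | None = None
    alpha: float = 0.05
    varmethod: Literal["normal", "wilson", "exact"] = "normal"
    decimal_points: int = 1
    miss_value_label: str = "."
    truth_direction: Direction = "ge"
    test_direction: Direction = "ge"
    zero_cell_correction: bool = True
    clip_wald: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.decimal_points < 0:
            raise ConfigError("decimal_points must be >= 0")
        if self.varmethod not in ("normal", "wilson", "exact"):
            raise ConfigError(
                f"varmethod must be one of 'normal', 'wilson', 'exact', got {self.varmethod!r}"
            )
        for d in (self.truth_direction, self.test_direction):
            if d not in ("ge", "le"):
                raise ConfigError(f"direction must be 'ge' or 'le', got {d!r}")


@dataclass
class SubjectTable:
    """Subject-level records with named truth/test/domain columns."""

    data: pd.DataFrame
    truth_column: str
    test_columns: list[str]
    domain_column: str | None = None

    def __post_init__(self) -> None:
        missing = [
            c
            for c in [self.truth_column, *self.test_columns]
            + ([self.domain_column] if self.domain_column else [])
            if c not in self.data.columns
        ]
        if missing:
            raise InputError(f"column(s) not found in data: {', '.join(missing)}")
        for col in [self.truth_column, *self.test_columns]:
            values = self.data[col]
            if not pd.api.types.is_numeric_dtype(values):
                bad = values[~values.isna() & pd.to_numeric(values, errors="coerce").isna()]
                if len(bad):
                    row = bad.index[0]
                    raise InputError(
                        f"non-numeric value {bad.iloc[0]!r} in column {col!r} at row {row}"
                    )
                self.data[col] = pd.to_numeric(values, errors="coerce")

    @property
    def n_rows(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-classification of dichotomized test result vs. true status."""

    a: int  # true positives
    b: int  # false positives
    c: int  # false negatives
    d: int  # true negatives
    excluded: int = 0  # rows dropped for missing truth/test values

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "excluded"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InputError(f"cell {name} must be a nonnegative integer, got {v!r}")

    @property
    def n1(self) -> int:
        """Test-positive margin a + b."""
        return self.a + self.b

    @property
    def n2(self) -> int:
        """Test-negative margin c + d."""
        return self.c + self.d

    @property
    def m1(self) -> int:
        """Truth-positive margin a + c."""
        return self.a + self.c

    @property
    def m2(self) -> int:
        """Truth-negative margin b + d."""
        return self.b + self.d

    @property
    def n(self) -> int:
        """Grand total."""
        return self.a + self.b + self.c + self.d

    def corrected(self) -> "ContinuityCorrectedTable":
        """Haldane-Anscombe table: 0.5 added to every cell."""
        return ContinuityCorrectedTable(
            self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5
        )

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class ContinuityCorrectedTable:
    """Non-integer cell counts used for zero-cell-corrected ratio measures."""

    a: float
    b: float
    c: float
    d: float

    n1 = ConfusionTable.n1
    n2 = ConfusionTable.n2
    m1 = ConfusionTable.m1
    m2 = ConfusionTable.m2
    n = ConfusionTable.n


def dichotomize(
    value: float | None, cutoff: float, direction: Direction = "ge"
) -> str | None:
    """Classify one numeric value against a cutoff.

    Returns ``"positive"`` when the value lies on the disease side of the
    cutoff (>= cutoff for the default ``ge`` direction, <= cutoff for
    ``le``), ``"negative"`` otherwise, and ``None`` for a missing value.
    """
    if not math.isfinite(cutoff):
        raise InputError(f"cutoff must be finite, got {cutoff}")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise InputError(f"cannot dichotomize non-numeric value {value!r}") from exc
    if direction == "ge":
        return "positive" if value >= cutoff else "negative"
    return "positive" if value <= cutoff else "negative"


def read_subject_table(
    path: str | Path,
    truth_column: str,
    test_columns: Sequence[str],
    domain_column: str | None = None,
    miss_value_label: str = ".",
) -> SubjectTable:
    """Load a delimited text file (CSV, or TSV by .tsv/.txt extension).

    The file must carry a header row naming ``truth_column`` and every entry
    of ``test_columns``. Empty fields, ``NA``, ``NaN`` and the configured
    missing label are treated as missing.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","
    try:
        frame = pd.read_csv(path, sep=sep, na_values=[miss_value_label], skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - malformed file edge
        raise InputError(f"could not parse {path}: {exc}") from exc
    return SubjectTable(
        data=frame,
        truth_column=truth_column,
        test_columns=list(test_columns),
        domain_column=domain_column,
    )


def parse_condition(expr: str) -> Callable[[pd.DataFrame], pd.Series]:
    """Compile a restricted row-filter string into a vectorized predicate.

    Grammar: one or more clauses ``column op number`` joined by ``and``,
    where op is one of == != < <= > >=. This deliberately mirrors a single
    IF-statement filter without evaluating arbitrary code.
    """
    clauses = []
    for raw in re.split(r"\band\b", expr):
        m = _CLAUSE_RE.match(raw)
        if m is None:
            raise ConfigError(
                f"cannot parse condition clause {raw.strip()!r}; expected 'column op number'"
            )
        col, op, value = m.group(1), m.group(2), float(m.group(3))
        clauses.append((col, _CONDITION_OPS[op], value))

    def predicate(frame: pd.DataFrame) -> pd.Series:
        mask = pd.Series(True, index=frame.index)
        for col, fn, value in clauses:
            if col not in frame.columns:
                raise ConfigError(f"condition references unknown column {col!r}")
            mask &= fn(frame[col], value)
        return mask

    return predicate


def apply_condition(table: SubjectTable, condition: str | Callable | None) -> SubjectTable:
    """Filter rows by a condition string or callable; None is a pass-through."""
    if condition is None:
        return table
    if isinstance(condition, str):
        mask = parse_condition(condition)(table.data)
    else:
        mask = table.data.apply(condition, axis=1).astype(bool)
    return replace(table, data=table.data.loc[mask])


def apply_domain_filter(table: SubjectTable, domain_value: float | None) -> SubjectTable:
    """Keep rows whose domain column equals ``domain_value`` (order preserved)."""
    if domain_value is None:
        return table
    if table.domain_column is None:
        raise ConfigError("domain_value supplied but no domain column is configured")
    mask = table.data[table.domain_column] == domain_value
    return replace(table, data=table.data.loc[mask])


def build_confusion_table(
    data: SubjectTable, test_column: str, config: AnalysisConfig
) -> ConfusionTable:
    """Cross-classify one test variable against the reference.

    Rows failing the condition or domain filter are removed first; rows
    missing either the truth value or this test's value are counted in
    ``excluded`` and omitted from the cells (per-test listwise deletion, so
    different tests may use different n).
    """
    if test_column not in data.test_columns:
        raise InputError(f"unknown test column {test_column!r}")
    filtered = apply_domain_filter(apply_condition(data, config.condition), config.domain_value)
    frame = filtered.data
    truth = frame[data.truth_column].to_numpy(dtype=float)
    test = frame[test_column].to_numpy(dtype=float)

    usable = ~(np.isnan(truth) | np.isnan(test))
    excluded = int((~usable).sum())
    truth, test = truth[usable], test[usable]
    if truth.size == 0:
        raise EmptyTableError(
            f"no usable rows for test {test_column!r} after filtering and exclusion"
        )

    t_pos = truth >= config.truth_cut if config.truth_direction == "ge" else truth <= config.truth_cut
    x_pos = test >= config.test_cut if config.test_direction == "ge" else test <= config.test_cut
    return ConfusionTable(
        a=int(np.sum(t_pos & x_pos)),
        b=int(np.sum(~t_pos & x_pos)),
        c=int(np.sum(t_pos & ~x_pos)),
        d=int(np.sum(~t_pos & ~x_pos)),
        excluded=excluded,
    )


def table_from_counts(a: int, b: int, c: int, d: int) -> ConfusionTable:
    """Build a ConfusionTable directly from the four cell counts."""
    return ConfusionTable(a=a, b=b, c=c, d=d)
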