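"""Publication-style tables and machine-readable exports.

One rendered block per diagnostic test, stacked: the block shows the test
and reference labels, the 2x2 contingency table with margins, and the 16
measure rows formatted "estimate (lower-upper)" at the configured number of
decimal places. Percent-scale measures are rescaled to 0-100 here and only
here; rounding is half-up to match conventional table formatting
(e.g. 170.97 -> 171.0 at one decimal).

Exports:
  <table_name>_dams.csv   tidy, one row per (test, measure), unrounded
  <table_name>_table.md   rendered Markdown table
  <table_name>_table.html rendered HTML table
  <table_name>_roc.csv / _pr.csv   long-format curve tables
  <table_name>_roc.svg / _pr.svg   optional overlay plots
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from .curves import Curve, overlay_tables, plot_overlay
from .errors import ConfigError
from .measures import MEASURE_LABELS, DamPanel, Estimate


@dataclass(frozen=True)
class ReportSpec:
    """Output-shaping parameters for one report."""

    table_name: str
    table_title: str = ""
    survey_name: str | None = None
    output_dir: str | Path = "."
    decimal_points: int = 1
    miss_value_label: str = "."
    print_output: bool = True

    def __post_init__(self) -> None:
        if self.decimal_points < 0:
            raise ConfigError("decimal_points must be >= 0")


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero (half-up), not banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(value: float, decimals: int) -> str:
    return f"{round_half_up(value, decimals):.{decimals}f}"


def format_estimate(est: Estimate, decimals: int, miss_label: str) -> str:
    """Render one estimate as "point (lower-upper)" on its display scale."""
    if not est.defined:
        return miss_label
    factor = 100.0 if est.scale == "percent" else 1.0
    text = _fmt(est.point * factor, decimals)
    if est.lower is not None and est.upper is not None:
        text += f" ({_fmt(est.lower * factor, decimals)}–{_fmt(est.upper * factor, decimals)})"
    return text


def panel_rows(panel: DamPanel, spec: ReportSpec) -> list[dict]:
    """Seven-column rows for one test block (2x2 cells beside measure rows)."""
    t = panel.table
    cells = [
        (">= cut", str(t.a), str(t.b), str(t.n1)),
        ("< cut", str(t.c), str(t.d), str(t.n2)),
        ("Total", str(t.m1), str(t.m2), str(t.n)),
    ]
    rows = []
    for i, est in enumerate(panel.estimates):
        result, pos, neg, total = cells[i] if i < len(cells) else ("", "", "", "")
        rows.append(
            {
                "Test": panel.test_name if i == 0 else "",
                "Test result": result,
                f"{panel.reference_name} +": pos,
                f"{panel.reference_name} -": neg,
                "Total": total,
                "Measure": MEASURE_LABELS[est.name],
                "Estimate (CI)": format_estimate(
                    est, spec.decimal_points, spec.miss_value_label
                ),
            }
        )
    return rows


def render_panel_table(panels: Sequence[DamPanel], spec: ReportSpec) -> pd.DataFrame:
    """Stack all test blocks into one display table."""
    if not panels:
        raise ConfigError("need at least one panel to render")
    rows = []
    for panel in panels:
        rows.extend(panel_rows(panel, spec))
    frame = pd.DataFrame(rows)
    # keep the reference-column headers of the first panel for the whole table
    return frame


def render_markdown(panels: Sequence[DamPanel], spec: ReportSpec) -> str:
    frame = render_panel_table(panels, spec)
    lines = []
    if spec.table_title:
        title = spec.table_title
        if spec.survey_name:
            title += f" ({spec.survey_name})"
        lines += [f"**{title}**", ""]
    lines.append("| " + " | ".join(frame.columns) + " |")
    lines.append("|" + "|".join(["---"] * len(frame.columns)) + "|")
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def tidy_frame(panels: Sequence[DamPanel]) -> pd.DataFrame:
    """One row per (test, measure) with exact unrounded values.

    Proportion/index values are kept on their natural scale (0-1 for
    proportions); parsing this file back reproduces every estimate exactly.
    """
    rows = []
    for panel in panels:
        for est in panel.estimates:
            rows.append(
                {
                    "test": panel.test_name,
                    "reference": panel.reference_name,
                    "measure": est.name,
                    "scale": est.scale,
                    "point": est.point,
                    "lower": est.lower,
                    "upper": est.upper,
                    "method": est.method,
                    "alpha": est.alpha,
                    "n": panel.table.n,
                    "excluded": panel.table.excluded,
                }
            )
    return pd.DataFrame(rows)


def export(
    panels: Sequence[DamPanel],
    curves: Sequence[Curve] = (),
    spec: ReportSpec = ReportSpec(table_name="report"),
    plots: bool = False,
) -> dict[str, Path]:
    """Write every report artifact; returns {artifact kind: path}.

    Raises before writing anything if the output directory is unusable.
    Rerunning with identical inputs produces byte-identical CSV files.
    """
    out = Path(spec.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise OSError(f"output_dir {out} is not a directory")
    prefix = out / spec.table_name

    written: dict[str, Path] = {}
    md = render_markdown(panels, spec)
    md_path = prefix.parent / f"{spec.table_name}_table.md"
    md_path.write_text(md)
    written["table_md"] = md_path

    html_path = prefix.parent / f"{spec.table_name}_table.html"
    html = render_panel_table(panels, spec).to_html(index=False)
    if spec.table_title:
        html = f"<h3>{spec.table_title}</h3>\n" + html
    html_path.write_text(html)
    written["table_html"] = html_path

    tidy_path = prefix.parent / f"{spec.table_name}_dams.csv"
    # 17 significant digits: float fields survive the round trip bit-exactly
    tidy_frame(panels).to_csv(tidy_path, index=False, float_format="%.17g")
    written["dams_csv"] = tidy_path

    for kind in ("roc", "pr"):
        group = [c for c in curves if c.kind == kind]
        if not group:
            continue
        csv_path = prefix.parent / f"{spec.table_name}_{kind}.csv"
        overlay_tables(group).to_csv(csv_path, index=False)
        written[f"{kind}_csv"] = csv_path
        if plots:
            svg_path = prefix.parent / f"{spec.table_name}_{kind}.svg"
            plot_overlay(group, str(svg_path))
            written[f"{kind}_svg"] = svg_path

    if spec.print_output:
        print(md)
    return written
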