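"""Per-species result tables, Average-row aggregation, and report rendering.

Summary tables in assembly studies conventionally append an Average row
that is the arithmetic mean of each per-species column — including
percentage columns, which are averaged *as percentages* (mean of the
per-species percentages).  The pooled alternative (summing numerators
and denominators before dividing) answers a different question and can
differ substantially when denominators vary across species, so
:func:`pooled_percentage` is computed and labeled alongside the mean.

Rounding is half away from zero, the convention of hand-rounded
printed tables (banker's rounding would disagree on exact halves).
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "load_published_table",
    "PUBLISHED_TABLES",
    "round_half_away",
    "aggregate_table",
    "pooled_percentage",
    "with_average_row",
    "render_report",
    "parse_report",
    "dotplot_coordinates",
]

PUBLISHED_TABLES = {
    "reads": "table2_reads.tsv",
    "assembly": "table3_assembly.tsv",
    "busco": "table4_busco.tsv",
    "polymorphisms": "table5_polymorphisms.tsv",
    "gap_closure": "table6_gap_closure.tsv",
}


def load_published_table(name: str) -> pd.DataFrame:
    """Load one of the transcribed per-species summary tables.

    Tables are keyed ``reads``, ``assembly``, ``busco``,
    ``polymorphisms`` and ``gap_closure``; each is indexed by species.
    Non-numeric placeholders ("n/a") become NaN.
    """
    if name not in PUBLISHED_TABLES:
        raise KeyError(f"unknown table {name!r}; choose from {sorted(PUBLISHED_TABLES)}")
    ref = resources.files("contig_audit.data") / PUBLISHED_TABLES[name]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="species", na_values=["n/a"])
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return df


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round half away from zero (printed-table convention)."""
    factor = 10.0**decimals
    scaled = value * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor


def aggregate_table(
    table: pd.DataFrame,
    column: str,
    subset: Optional[Sequence[str]] = None,
    decimals: int = 0,
) -> float:
    """Average-row entry for one column: mean of the selected rows.

    Percent columns are averaged as percentages — each species
    contributes its own percentage with equal weight, regardless of the
    size of its denominator.  ``subset`` selects species ids; the
    selection must be non-empty and the column numeric.
    """
    if column not in table.columns:
        raise KeyError(f"no column {column!r}")
    series = table[column] if subset is None else table.loc[list(subset), column]
    series = series.dropna()
    if series.empty:
        raise ValueError("empty selection")
    if not pd.api.types.is_numeric_dtype(series):
        raise TypeError(f"column {column!r} is not numeric")
    return round_half_away(float(series.mean()), decimals)


def pooled_percentage(
    table: pd.DataFrame, numerator: str, denominator: str, decimals: int = 0
) -> float:
    """Σnumerator / Σdenominator as a percent — the pooled convention."""
    num = table[numerator].dropna().sum()
    den = table[denominator].dropna().sum()
    if den <= 0:
        raise ValueError("pooled denominator is not positive")
    return round_half_away(100.0 * num / den, decimals)


def with_average_row(
    table: pd.DataFrame, decimals: dict[str, int] | int = 1, label: str = "Average"
) -> pd.DataFrame:
    """Append an Average row; ``decimals`` may be per-column or global."""
    row = {}
    for col in table.columns:
        if pd.api.types.is_numeric_dtype(table[col].dropna()):
            d = decimals[col] if isinstance(decimals, dict) else decimals
            try:
                row[col] = aggregate_table(table, col, decimals=d)
            except ValueError:
                row[col] = float("nan")
        else:
            row[col] = ""
    out = table.copy()
    out.loc[label] = pd.Series(row)
    return out


def render_report(
    tables: dict[str, pd.DataFrame],
    out: str | Path,
    fmt: str = "tsv",
    average: bool = True,
) -> list[Path]:
    """Write each table to ``<out>/<name>.(tsv|md)`` deterministically.

    Column order is preserved, tables are written in sorted-name order,
    and re-rendering identical inputs is byte-identical.  Returns the
    paths written.
    """
    if fmt not in ("tsv", "markdown"):
        raise ValueError("format must be 'tsv' or 'markdown'")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        table = tables[name]
        if table.empty:
            continue
        rendered = with_average_row(table) if average else table
        path = out / f"{name}.{'tsv' if fmt == 'tsv' else 'md'}"
        try:
            if fmt == "tsv":
                rendered.to_csv(path, sep="\t")
            else:
                path.write_text(rendered.to_markdown() + "\n")
        except OSError as err:
            raise OSError(f"failed writing report table to {path}: {err}") from err
        written.append(path)
    return written


def parse_report(path: str | Path) -> pd.DataFrame:
    """Read back a TSV report table (inverse of tsv rendering)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def dotplot_coordinates(placements: Iterable, scaffold_offsets: dict[str, int]) -> pd.DataFrame:
    """Placement segments as dot-plot coordinates.

    x is the placement's span offset into the concatenated reference
    scaffolds, y its span on the assembly contig; one row per segment
    end (two per placement) so the segments plot as connected pairs.
    """
    rows = []
    for p in placements:
        scaffold_id = p.query_id.rsplit(".", 1)[0]
        base = scaffold_offsets.get(scaffold_id, 0)
        y0, y1 = (p.t_start, p.t_end) if p.strand == "+" else (p.t_end, p.t_start)
        rows.append(
            dict(query_id=p.query_id, target_id=p.target_id,
                 x0=base + p.q_start, x1=base + p.q_end, y0=y0, y1=y1,
                 strand=p.strand, identity=p.identity)
        )
    return pd.DataFrame(rows)
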