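"""Tabular output helpers and the HPLC re-glucosylation quantification.

All tables the CLI writes go through :func:`format_table` so that the
column order and float formatting (6 significant digits) are fixed and
output files are byte-for-byte reproducible from the same inputs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["reglucosylation_percent", "format_float", "write_table"]


def reglucosylation_percent(area_glc1: float, area_man9: float) -> float:
    """Percent glucosylation from HPLC peak areas.

    The assay releases the two N-glycan species Glc1Man9GlcNAc2 and
    Man9GlcNAc2; the readout is the Glc1 peak area as a percentage of the
    total of the two species: ``100 * glc1 / (glc1 + man9)``.
    """
    if area_glc1 < 0 or area_man9 < 0:
        raise ValueError("peak areas must be non-negative")
    total = area_glc1 + area_man9
    if total == 0:
        raise ValueError("both peak areas are zero: percent undefined")
    return 100.0 * area_glc1 / total


def format_float(x) -> str:
    """6-significant-digit float rendering used in every TSV the CLI writes."""
    if x is None or (isinstance(x, float) and x != x):
        return "NA"
    return f"{float(x):.6g}"


def write_table(df: pd.DataFrame, path: str | Path | None) -> str:
    """Render a DataFrame as TSV with fixed float formatting; write it if
    a path is given, and return the text either way."""
    text = df.to_csv(sep="\t", index=False, float_format="%.6g")
    if path is not None:
        Path(path).write_text(text)
    return text
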