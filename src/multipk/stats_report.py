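"""Accuracy and precision statistics for calculated pK values.

Accuracy: mean absolute deviation and root-mean-square deviation between a
calculated pK column and the experimental one, with the Null model (every
site predicted at its model-compound pK) as the no-structure baseline.
Precision: for a homodimer, the signed difference ΔpK between the pK₁/₂ of
homologous sites in the two chains, and its mean absolute value — symmetry
demands zero, so |ΔpK|_av measures the reproducibility of the protocol.
"""
from __future__ import annotations

import io
import logging
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "mean_abs_dev",
    "rmsd",
    "chain_delta_summary",
    "null_model",
    "load_benchmark_table",
    "pk_table",
    "format_report",
]


def _align(column_a, column_b) -> tuple:
    a = pd.Series(column_a, dtype=float)
    b = pd.Series(column_b, dtype=float)
    if set(a.index) != set(b.index):
        extra_a = sorted(set(a.index) - set(b.index))
        extra_b = sorted(set(b.index) - set(a.index))
        raise ValueError(f"site sets differ: only in a={extra_a}, only in b={extra_b}")
    b = b.reindex(a.index)
    mask = a.notna() & b.notna()
    dropped = int((~mask).sum())
    if dropped:
        logger.info("excluding %d sites with missing values from deviation statistics", dropped)
    if mask.sum() == 0:
        raise ValueError("no overlapping finite values")
    return a[mask], b[mask]


def mean_abs_dev(column_a, column_b) -> float:
    """Mean absolute deviation (1/n)·Σ|a−b| in pH units."""
    a, b = _align(column_a, column_b)
    return float(np.abs(a - b).mean())


def rmsd(column_a, column_b, denominator_policy: str = "n") -> float:
    """Root-mean-square deviation; denominator n (default) or n−1."""
    a, b = _align(column_a, column_b)
    d2 = ((a - b) ** 2).sum()
    n = len(a)
    if denominator_policy == "n":
        return float(np.sqrt(d2 / n))
    if denominator_policy == "n-1":
        if n < 2:
            raise ValueError("n-1 denominator needs at least two sites")
        return float(np.sqrt(d2 / (n - 1)))
    raise ValueError(f"unknown denominator policy {denominator_policy!r}")


def chain_delta_summary(pk_results) -> tuple:
    """Signed per-site ΔpK between paired chains and the mean |ΔpK|.

    ``pk_results`` is a DataFrame (or mapping) with one row per homologous
    site and exactly two columns, one per chain; returns
    (Series of ΔpK = first − second, |ΔpK|_av).
    """
    df = pd.DataFrame(pk_results)
    if df.shape[1] != 2:
        raise ValueError(f"need exactly two chain columns, got {list(df.columns)}")
    unpaired = df.index[df.isna().any(axis=1)].tolist()
    if unpaired:
        raise ValueError(f"unpaired sites: {unpaired}")
    delta = df.iloc[:, 0] - df.iloc[:, 1]
    delta.name = "delta_pk"
    return delta, float(np.abs(delta).mean())


def null_model(sites) -> pd.Series:
    """The Null model column: every site predicted at its model pK.

    Accepts a sequence of site objects with ``pk_mod`` (indexed by site_id)
    or a mapping/Series of pk_mod values.
    """
    try:
        return pd.Series({s.site_id: s.pk_mod for s in sites}, name="pk_mod", dtype=float)
    except AttributeError:
        return pd.Series(sites, name="pk_mod", dtype=float)


def load_benchmark_table() -> pd.DataFrame:
    """Bundled GCN4 leucine-zipper pK benchmark (16 sites, 5 columns)."""
    ref = resources.files("multipk.data") / "gcn4_pk_benchmark.tsv"
    df = pd.read_csv(io.StringIO(ref.read_text()), sep="\t", comment="#",
                     index_col="site")
    return df


def pk_table(rows: Mapping, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Normalise a mapping site_id -> {column: value} into a PK table."""
    df = pd.DataFrame.from_dict(rows, orient="index")
    if columns:
        df = df[list(columns)]
    return df.sort_index()


def format_report(df: pd.DataFrame, aggregates: Mapping[str, Mapping] | None = None) -> str:
    """Byte-stable text report: sorted sites, 2-decimal pK values."""
    df = df.sort_index()
    lines = ["site\t" + "\t".join(str(c) for c in df.columns)]
    for idx, row in df.iterrows():
        key = ":".join(str(x) for x in idx) if isinstance(idx, tuple) else str(idx)
        vals = "\t".join("" if pd.isna(v) else f"{v:.2f}" for v in row)
        lines.append(f"{key}\t{vals}")
    for name, per_col in (aggregates or {}).items():
        vals = "\t".join(
            "" if c not in per_col or pd.isna(per_col[c]) else f"{per_col[c]:.2f}"
            for c in df.columns
        )
        lines.append(f"{name}\t{vals}")
    return "\n".join(lines) + "\n"
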