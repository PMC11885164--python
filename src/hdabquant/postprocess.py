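"""Post-processing of per-slide results files.

Parses the detection-level TSV exports of a batch run, joins the blinded
scanner ids with the sample inventory, aggregates per
(sample, antibody, image, region) positivity rates, computes
pairwise-complete correlation matrices across markers and renders
heatmaps/scatterplots.

Vendor whole-slide suffixes (.mrxs/.ndpi/.czi/.bif) are honoured as naming
dialects only: they are stripped to recover ``ID_Slidescanning``.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .batch import RESULTS_COLUMNS
from .detection import LABEL_NEGATIVE, LABEL_NOCELL, LABEL_POSITIVE
from .errors import DialectError, HdabQuantError, IntegrityError

log = logging.getLogger(__name__)

VENDOR_SUFFIXES = (".mrxs", ".ndpi", ".czi", ".bif")
KEY_COLUMN = "ID_Slidescanning"


def strip_vendor_suffix(name: str) -> str:
    """``A.mrxs`` -> ``A``; unknown suffixes are left alone."""
    stem = name
    for suf in VENDOR_SUFFIXES:
        if stem.lower().endswith(suf):
            return stem[: -len(suf)]
    return stem


def parse_results(folder, dialect_columns=RESULTS_COLUMNS) -> pd.DataFrame:
    """Concatenate every ``*.txt`` results file in ``folder``.

    Adds an ``ID_Slidescanning`` column derived from the file name (vendor
    suffixes stripped).  Malformed rows (wrong field count, unparsable
    numbers) are skipped with a logged count; an unknown header raises
    :class:`DialectError`.
    """
    folder = Path(folder)
    files = sorted(folder.glob("*.txt"))
    if not files:
        raise HdabQuantError(f"no results files (*.txt) in {folder}")
    frames = []
    n_skipped = 0
    required = set(dialect_columns)
    numeric = [c for c in dialect_columns if c not in
               ("Image", "Object ID", "Classification", "Parent")]
    for f in files:
        with open(f, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
        unknown = [c for c in header if c not in required]
        if unknown:
            raise DialectError(
                f"{f.name}: unknown column(s) {unknown}; expected the "
                "documented results dialect"
            )
        missing = [c for c in dialect_columns if c not in header]
        if missing:
            raise DialectError(f"{f.name}: missing column(s) {missing}")
        bad = []
        df = pd.read_csv(
            f, sep="\t", dtype=str,
            on_bad_lines=lambda row, _bad=bad: _bad.append(row) or None,
            engine="python",
        )
        n_skipped += len(bad)
        coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
        bad_rows = coerced.isna().all(axis=1) & df[numeric].notna().any(axis=1)
        n_skipped += int(bad_rows.sum())
        df = df[~bad_rows].copy()
        df[numeric] = coerced[~bad_rows]
        df[KEY_COLUMN] = strip_vendor_suffix(f.stem)
        df["Image"] = df["Image"].map(strip_vendor_suffix)
        frames.append(df)
    if n_skipped:
        log.warning("skipped %d malformed row(s) while parsing results", n_skipped)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_skipped"] = n_skipped
    return out


def read_inventory(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        inv = pd.read_excel(path)
    else:
        inv = pd.read_csv(path)
    if KEY_COLUMN not in inv.columns:
        raise DialectError(f"inventory lacks required column {KEY_COLUMN!r}")
    return inv


def merge_inventory(detections: pd.DataFrame, inventory: pd.DataFrame) -> pd.DataFrame:
    """Left-join detections with the inventory on ``ID_Slidescanning``.

    Row count is conserved; scan ids missing from the inventory are kept
    with missing metadata and reported.  Duplicate inventory keys raise
    :class:`IntegrityError`.
    """
    dup = inventory[KEY_COLUMN][inventory[KEY_COLUMN].duplicated()].unique()
    if len(dup):
        raise IntegrityError(f"duplicate inventory keys: {sorted(map(str, dup))}")
    merged = detections.merge(inventory, on=KEY_COLUMN, how="left", validate="m:1")
    meta_cols = [c for c in inventory.columns if c != KEY_COLUMN]
    if meta_cols:
        unmatched = merged.loc[merged[meta_cols[0]].isna(), KEY_COLUMN].unique()
        if len(unmatched):
            log.warning("scan id(s) not in inventory: %s", sorted(map(str, unmatched)))
            merged.attrs["unmatched"] = sorted(map(str, unmatched))
    return merged


def positivity_table(merged: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, antibody, image, region) class counts and rates.

    NoCell detections never enter the rate; groups with no countable cells
    get a missing rate and ``undefined=True``.
    """
    if "Classification" not in merged.columns:
        raise DialectError("Classification column required")
    df = merged.copy()
    group_cols = [c for c in ("sample_id", "antibody") if c in df.columns]
    group_cols += [KEY_COLUMN, "Parent"]
    rows = []
    for key, g in df.groupby(group_cols, dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n_pos = int((g["Classification"] == LABEL_POSITIVE).sum())
        n_neg = int((g["Classification"] == LABEL_NEGATIVE).sum())
        n_no = int((g["Classification"] == LABEL_NOCELL).sum())
        denom = n_pos + n_neg
        rows.append(
            dict(zip(group_cols, key))
            | {
                "n_positive": n_pos,
                "n_negative": n_neg,
                "n_nocell": n_no,
                "positivity_rate": (100.0 * n_pos / denom) if denom else np.nan,
                "undefined": denom == 0,
            }
        )
    return pd.DataFrame(rows)


def write_positivity_table(table: pd.DataFrame, path):
    """Write CSV or XLSX depending on the extension."""
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        table.to_excel(path, index=False)
    else:
        table.to_csv(path, index=False)
    return path


def marker_matrix(
    table: pd.DataFrame, sample_col: str = "sample_id", exclude_pooled_region: bool = True
) -> pd.DataFrame:
    """Pivot the positivity table to samples x markers (antibody x region)."""
    df = table.copy()
    if exclude_pooled_region and "Parent" in df.columns:
        df = df[df["Parent"] != "ALL"]
    marker = df["antibody"].astype(str)
    if "Parent" in df.columns and df["Parent"].nunique() > 1:
        marker = marker + ":" + df["Parent"].astype(str)
    df = df.assign(marker=marker)
    return df.pivot_table(
        index=sample_col, columns="marker", values="positivity_rate", aggfunc="mean"
    )


def correlation_matrix(m: pd.DataFrame, method: str = "pearson", min_n: int = 3):
    """Pairwise-complete correlations between marker columns.

    Returns ``(corr, n)`` where ``n`` counts complete pairs per entry.
    Entries with fewer than ``min_n`` complete pairs, or involving a
    constant column, are missing.
    """
    if method not in ("pearson", "spearman", "kendall"):
        raise HdabQuantError(f"unknown correlation method {method!r}")
    if m.shape[1] < 2:
        raise HdabQuantError("need at least 2 markers")
    const = [c for c in m.columns if m[c].dropna().nunique() <= 1]
    if const:
        warnings.warn(f"constant marker column(s): {const}", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = m.corr(method=method, min_periods=min_n)
    notna = m.notna().astype(int)
    n = notna.T @ notna
    corr[n < min_n] = np.nan
    for c in const:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr, n


def render_outputs(m: pd.DataFrame, corr: pd.DataFrame, outdir) -> list:
    """Correlation heatmap + one scatterplot per marker pair.

    Deterministic names: ``correlation_heatmap.png`` and
    ``<markerA>_vs_<markerB>.png``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    fig, ax = plt.subplots(figsize=(1.2 * len(corr) + 2, 1.0 * len(corr) + 2))
    sns.heatmap(corr, annot=True, fmt=".2f", vmin=-1, vmax=1, cmap="vlag", ax=ax)
    fig.tight_layout()
    p = outdir / "correlation_heatmap.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    def safe(name):
        return "".join(ch if (ch.isalnum() or ch in "-_") else "-" for ch in str(name))

    for a, b in combinations(m.columns, 2):
        sub = m[[a, b]].dropna()
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(sub[a], sub[b], s=20)
        ax.set_xlabel(f"{a} positivity (%)")
        ax.set_ylabel(f"{b} positivity (%)")
        fig.tight_layout()
        p = outdir / f"{safe(a)}_vs_{safe(b)}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written
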