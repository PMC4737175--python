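"""16x16 mismatch-fidelity grids assembled from per-pool yield tables.

Rows are splint junction dinucleotides (3'-NN-5', upstream-pairing base
first); columns are the 16 ligation products U/pD.  Cell values are
normalized yields (product fraction of total reporter fluorescence divided
by the 0.25 ceiling).  Yields are binned into the standard color scheme:
green > 80% of maximum, yellow 50-80%, red 10-50%, gray 2-10%, open for a
called peak below 2%, none when no peak was called.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import BASES, DM, DOUBLE, UM, WC, PanelDesign, complement
from .trace_analysis import PoolYieldTable

#: Row labels: splint 3'-NN-5' dinucleotides, ordered so that each row's
#: fully complementary (WC) product falls on the main diagonal when the
#: columns run in elution order A/pA ... T/pT: the first row is the splint
#: whose WC product is A/pA (3'-TT-5'), and so on.
ROW_LABELS = tuple(
    complement(u) + complement(d) for u, d in itertools.product(BASES, BASES)
)
#: Column labels: products A/pA ... T/pT in standards-run elution order.
COL_LABELS = tuple(f"{u}/p{d}" for u, d in itertools.product(BASES, BASES))

BIN_ORDER = ("none", "open", "gray", "red", "yellow", "green")
_BIN_COLORS = {
    "green": "#2ca02c", "yellow": "#ffd92f", "red": "#d62728", "gray": "#9e9e9e"
}


def color_bin(normalized_yield: float, called: bool = True) -> str:
    """Bin a normalized yield into the grid color scheme.

    Intervals are half-open (low, high]: green > 0.80, yellow (0.50, 0.80],
    red (0.10, 0.50], gray (0.02, 0.10], open for a called peak <= 0.02,
    and none when no peak was called at all.
    """
    if normalized_yield < 0:
        raise ValueError("normalized yield must be non-negative")
    if not called:
        return "none"
    if normalized_yield > 0.80:
        return "green"
    if normalized_yield > 0.50:
        return "yellow"
    if normalized_yield > 0.10:
        return "red"
    if normalized_yield > 0.02:
        return "gray"
    return "open"


@dataclass
class FidelityMatrix:
    """Normalized-yield grid with a called-peak mask and optional SDs."""

    values: pd.DataFrame  # 16x16, rows ROW_LABELS, columns COL_LABELS
    called: pd.DataFrame  # boolean mask, same shape
    sd: pd.DataFrame | None = None

    def __post_init__(self):
        for df in (self.values, self.called):
            if list(df.index) != list(ROW_LABELS) or list(df.columns) != list(COL_LABELS):
                raise ValueError("matrix labels must be the 16 splint rows x 16 products")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("normalized yields must be non-negative")

    def bins(self) -> pd.DataFrame:
        out = pd.DataFrame(index=list(ROW_LABELS), columns=list(COL_LABELS), dtype=object)
        for r in ROW_LABELS:
            for c in COL_LABELS:
                out.loc[r, c] = color_bin(self.values.loc[r, c], self.called.loc[r, c])
        return out


def classify_cells(panel: PanelDesign | None = None) -> pd.DataFrame:
    """Category (WC/UM/DM/DOUBLE) of every grid cell.

    For row N1N2 and column U/pD: the upstream pair is U:N1 and the
    downstream pair pD:N2; a side is matched when probe and splint bases
    are complementary.  The classification depends only on junction bases,
    so the panel argument is accepted for interface symmetry.
    """
    out = pd.DataFrame(index=list(ROW_LABELS), columns=list(COL_LABELS), dtype=object)
    for row in ROW_LABELS:
        n1, n2 = row[0], row[1]
        for col in COL_LABELS:
            u, d = col.split("/p")
            up_ok = n1 == complement(u)
            down_ok = n2 == complement(d)
            out.loc[row, col] = WC if (up_ok and down_ok) else (
                UM if down_ok else (DM if up_ok else DOUBLE)
            )
    return out


def assemble_matrix(
    tables: Sequence[PoolYieldTable] | Mapping[str, PoolYieldTable],
    panel: PanelDesign,
) -> FidelityMatrix:
    """Stack 16 pool yield tables into the fidelity grid.

    Cell (splint NN, product U/pD) takes the normalized yield of that
    product in that pool; a product without a called peak contributes 0
    with the called mask cleared.
    """
    if isinstance(tables, Mapping):
        by_pool = dict(tables)
    else:
        by_pool = {}
        for t in tables:
            if t.pool in by_pool:
                raise ValueError(f"duplicate yield table for pool {t.pool}")
            by_pool[t.pool] = t
    missing = [r for r in ROW_LABELS if r not in by_pool]
    if missing:
        raise ValueError(f"missing yield tables for pools: {missing}")

    values = pd.DataFrame(0.0, index=list(ROW_LABELS), columns=list(COL_LABELS))
    called = pd.DataFrame(False, index=list(ROW_LABELS), columns=list(COL_LABELS))
    sds = pd.DataFrame(np.nan, index=list(ROW_LABELS), columns=list(COL_LABELS))
    for row in ROW_LABELS:
        table = by_pool[row]
        for col in COL_LABELS:
            u, d = col.split("/p")
            values.loc[row, col] = table.normalized_yield(u, d)
            called.loc[row, col] = table.product_called(u, d)
            sub = table.table[table.table.species == col]
            if len(sub) and np.isfinite(sub.sd.iloc[0]):
                sds.loc[row, col] = sub.sd.iloc[0] / 0.25
    has_sd = bool(np.isfinite(sds.to_numpy()).any())
    return FidelityMatrix(values, called, sds if has_sd else None)


@dataclass
class ProfileSummary:
    mean_wc_yield: float
    category_counts: dict[str, int]  # called cells per category (non-WC)
    category_totals: dict[str, float]  # summed normalized yield per category
    detected_mismatches: list[dict]  # pair notation + bin for non-WC cells

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def summarize(matrix: FidelityMatrix, categories: pd.DataFrame) -> ProfileSummary:
    """Aggregate the grid by junction category.

    Lists every non-WC cell binned gray or better, identified by its
    mismatched junction pair(s) in N:N / pN:N notation.
    """
    bins = matrix.bins()
    wc_vals = []
    counts = {UM: 0, DM: 0, DOUBLE: 0}
    totals = {UM: 0.0, DM: 0.0, DOUBLE: 0.0}
    detected = []
    rank = {b: i for i, b in enumerate(BIN_ORDER)}
    for row in ROW_LABELS:
        n1, n2 = row[0], row[1]
        for col in COL_LABELS:
            cat = categories.loc[row, col]
            val = matrix.values.loc[row, col]
            called = bool(matrix.called.loc[row, col])
            if cat == WC:
                if called:
                    wc_vals.append(val)
                continue
            if called:
                counts[cat] += 1
                totals[cat] += val
            if rank[bins.loc[row, col]] >= rank["gray"]:
                u, d = col.split("/p")
                pairs = []
                if n1 != complement(u):
                    pairs.append(f"{u}:{n1}")
                if n2 != complement(d):
                    pairs.append(f"p{d}:{n2}")
                detected.append(
                    {"row": row, "product": col, "category": cat,
                     "pairs": pairs, "bin": bins.loc[row, col], "yield": float(val)}
                )
    return ProfileSummary(
        mean_wc_yield=float(np.mean(wc_vals)) if wc_vals else 0.0,
        category_counts=counts,
        category_totals={k: float(v) for k, v in totals.items()},
        detected_mismatches=detected,
    )


def grid_text(matrix: FidelityMatrix) -> str:
    """Terminal rendering of the grid: one glyph per bin."""
    glyph = {"green": "G", "yellow": "Y", "red": "R", "gray": "g",
             "open": "o", "none": "."}
    bins = matrix.bins()
    width = max(len(c) for c in COL_LABELS)
    header = "     " + " ".join(c.rjust(width) for c in COL_LABELS)
    lines = [header]
    for row in ROW_LABELS:
        cells = " ".join(glyph[bins.loc[row, c]].rjust(width) for c in COL_LABELS)
        lines.append(f"{row}   {cells}")
    lines.append("legend: G>80%  Y 50-80%  R 10-50%  g 2-10%  o <2%  . not called")
    return "\n".join(lines)


def render_grid(matrix: FidelityMatrix, categories: pd.DataFrame, path) -> str:
    """Write the dot-grid figure (vector format decided by the suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = matrix.bins()
    fig, ax = plt.subplots(figsize=(9, 9))
    for i, row in enumerate(ROW_LABELS):
        for j, col in enumerate(COL_LABELS):
            b = bins.loc[row, col]
            y = len(ROW_LABELS) - 1 - i
            if b == "none":
                continue
            if b == "open":
                ax.scatter(j, y, s=90, facecolors="none", edgecolors="black",
                           linewidths=0.8)
            else:
                ax.scatter(j, y, s=90, color=_BIN_COLORS[b])
    ax.set_xticks(range(16), COL_LABELS, rotation=90, fontsize=8)
    ax.set_yticks(range(16), list(reversed(ROW_LABELS)), fontsize=8)
    ax.set_xlim(-0.5, 15.5)
    ax.set_ylim(-0.5, 15.5)
    ax.set_xlabel("ligation product (upstream/p-downstream)")
    ax.set_ylabel("splint junction, 3'-NN-5'")
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=_BIN_COLORS[b],
                   label={"green": ">80%", "yellow": "50-80%", "red": "10-50%",
                          "gray": "2-10%"}[b])
        for b in ("green", "yellow", "red", "gray")
    ]
    handles.append(plt.Line2D([], [], marker="o", ls="", markerfacecolor="none",
                              color="black", label="<2% (called)"))
    ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(1.01, 1.0),
              title="% of max yield", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)


@dataclass
class ProfileDiff:
    deltas: pd.DataFrame  # b - a, per cell
    bin_changes: list[dict]
    category_total_deltas: dict[str, float]


def compare_profiles(a: FidelityMatrix, b: FidelityMatrix) -> ProfileDiff:
    """Per-cell differences between two fidelity grids (b minus a)."""
    if list(a.values.index) != list(b.values.index) or (
        list(a.values.columns) != list(b.values.columns)
    ):
        raise ValueError("matrices carry different labels")
    deltas = b.values - a.values
    bins_a, bins_b = a.bins(), b.bins()
    changes = []
    for row in ROW_LABELS:
        for col in COL_LABELS:
            if bins_a.loc[row, col] != bins_b.loc[row, col]:
                changes.append({"row": row, "product": col,
                                "from": bins_a.loc[row, col],
                                "to": bins_b.loc[row, col],
                                "delta": float(deltas.loc[row, col])})
    cats = classify_cells()
    cat_deltas = {}
    for cat in (WC, UM, DM, DOUBLE):
        mask = (cats == cat).to_numpy()
        cat_deltas[cat] = float(deltas.to_numpy()[mask].sum())
    return ProfileDiff(deltas, changes, cat_deltas)


def matrix_to_tsv(matrix: FidelityMatrix) -> str:
    return matrix.values.to_csv(sep="\t")


def matrix_to_json(matrix: FidelityMatrix) -> str:
    bins = matrix.bins()
    doc = {
        "rows": list(ROW_LABELS),
        "columns": list(COL_LABELS),
        "values": matrix.values.to_numpy().tolist(),
        "called": matrix.called.to_numpy().tolist(),
        "bins": bins.to_numpy().tolist(),
    }
    if matrix.sd is not None:
        doc["sd"] = matrix.sd.to_numpy().tolist()
    return json.dumps(doc, indent=2)
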