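"""Table and heatmap export for ranked screens.

The heatmap shows the inhibition profiles of the top-ranked compounds
(one table page), rows in ranked order, columns the full kinase panel.
Colors run black (no inhibition) through yellow (moderate) to red
(maximal); unprofiled cells are grey.  Every rendered figure gets a numeric
twin — the exact submatrix displayed — written alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap, Normalize

from .errors import ValidationError
from .matrix import InhibitionMatrix

SUPPORTED_FORMATS = ("png", "svg", "pdf")

#: Default anchors: black at 0, yellow at the 50 midpoint, red at 100.
DEFAULT_COLOR_STOPS = ((0.0, "black"), (50.0, "yellow"), (100.0, "red"))


@dataclass(frozen=True)
class HeatmapSpec:
    """Rendering parameters: page size, color anchors, output format."""

    page_size: int = 10
    color_stops: tuple[tuple[float, str], ...] = DEFAULT_COLOR_STOPS
    fmt: str = "png"
    missing_color: str = "0.6"  # grey for unprofiled cells

    def __post_init__(self):
        if self.page_size < 1:
            raise ValidationError("page_size must be >= 1")
        if self.fmt not in SUPPORTED_FORMATS:
            raise ValidationError(
                f"unsupported heatmap format {self.fmt!r}; choose from {SUPPORTED_FORMATS}"
            )
        stops = sorted(v for v, _ in self.color_stops)
        if not stops or stops[0] != 0.0 or stops[-1] != 100.0:
            raise ValidationError("color stops must anchor both 0 and 100")

    def colormap(self) -> LinearSegmentedColormap:
        anchors = sorted(self.color_stops)
        cmap = LinearSegmentedColormap.from_list(
            "inhibition", [(v / 100.0, c) for v, c in anchors]
        )
        cmap.set_bad(self.missing_color)
        return cmap


def heatmap_submatrix(
    matrix: InhibitionMatrix, ranked: pd.DataFrame, spec: HeatmapSpec
) -> pd.DataFrame:
    """The numeric submatrix a heatmap displays: top page in ranked order.

    Values are taken from the input matrix untransformed, so this frame is
    the figure's exact data twin.
    """
    if ranked.empty:
        raise ValidationError("ranked table is empty; nothing to draw")
    top = ranked["compound_id"].head(spec.page_size).tolist()
    return matrix.data.loc[top]


def build_heatmap(
    matrix: InhibitionMatrix,
    ranked: pd.DataFrame,
    spec: HeatmapSpec,
    out_path: str | Path,
) -> tuple[Path, Path]:
    """Render the top-page heatmap and write its numeric twin.

    Returns (figure path, data path).  The data twin is a CSV of the exact
    displayed submatrix, written next to the figure with suffix ``.data.csv``.
    """
    out_path = Path(out_path)
    sub = heatmap_submatrix(matrix, ranked, spec)

    n_rows, n_cols = sub.shape
    fig_w = max(6.0, min(24.0, 0.18 * n_cols + 2.0))
    fig_h = max(2.5, 0.4 * n_rows + 1.5)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    mesh = ax.imshow(
        sub.to_numpy(dtype=float),
        cmap=spec.colormap(),
        norm=Normalize(vmin=0.0, vmax=100.0),
        aspect="auto",
        interpolation="nearest",
    )
    ax.set_yticks(range(n_rows), labels=sub.index)
    if n_cols <= 60:
        ax.set_xticks(range(n_cols), labels=sub.columns, rotation=90, fontsize=6)
    else:
        ax.set_xticks([])
        ax.set_xlabel(f"{n_cols} kinases")
    ax.set_title(f"Inhibition profiles — top {n_rows} by selectivity score")
    fig.colorbar(mesh, ax=ax, label="percent inhibition", shrink=0.8)
    fig.tight_layout()
    fig.savefig(out_path, format=spec.fmt, dpi=150)
    plt.close(fig)

    data_path = out_path.with_suffix(out_path.suffix + ".data.csv")
    sub.to_csv(data_path, na_rep="NA", index_label="compound")
    return out_path, data_path


def write_ranked_table(ranked: pd.DataFrame, path: str | Path, *, sep: str = ",") -> None:
    """Write the ranked score table in its documented column order."""
    ranked.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.6g")


def write_offtarget_table(records: pd.DataFrame, path: str | Path, *, sep: str = ",") -> None:
    """Write the significant-off-target table (compound, kinase, inhibition, ratio)."""
    records.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.6g")
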