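"""Cross-condition comparison of enrichment tables.

The study compares the enriched hexamers of three contrasts (osmotic vs
control, salt vs control, osmotic vs salt) by overlaying their Z-score
rankings: which motifs sit in the top 10 of both conditions, and which are
condition-specific.  "Top" membership is operationalized as rank <= 10 by
z (optionally further filtered by a minimum z).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import EnrichmentTable


def _top_motifs(table: EnrichmentTable, k: int, z_min: float | None) -> list[str]:
    head = table.top_k(k)
    if z_min is not None:
        head = head[head["z"] >= z_min]
    return list(head.index)


@dataclass
class ContrastComparison:
    """Aligned per-hexamer Z-scores of two contrasts with top-set overlap.

    ``df`` is indexed by motif with columns freq_x, z_x, top_x, freq_y,
    z_y, top_y and delta = z_y - z_x (NaN where either z is undefined).
    """

    name_x: str
    name_y: str
    df: pd.DataFrame
    shared_top: list[str]
    specific_top_x: list[str]
    specific_top_y: list[str]

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.insert(0, "motif", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def compare(
    table_a: EnrichmentTable,
    table_b: EnrichmentTable,
    k: int = 10,
    z_min: float | None = None,
) -> ContrastComparison:
    """Align two enrichment tables and partition their top-k memberships.

    A motif with undefined z in one table is excluded from delta but stays
    eligible for the other table's top set.  Both tables must have been
    standardized to the same per-sample_size scale.
    """
    if table_a.sample_size != table_b.sample_size:
        raise ValueError("tables standardized to different sample sizes")
    if not table_a.df.index.equals(table_b.df.index):
        raise ValueError("mismatched hexamer universes")

    top_x = _top_motifs(table_a, k, z_min)
    top_y = _top_motifs(table_b, k, z_min)
    shared = [m for m in top_x if m in set(top_y)]
    df = pd.DataFrame(
        {
            "freq_x": table_a.df["observed_freq"],
            "z_x": table_a.df["z"],
            "top_x": table_a.df.index.isin(top_x),
            "freq_y": table_b.df["observed_freq"],
            "z_y": table_b.df["z"],
            "top_y": table_b.df.index.isin(top_y),
        },
        index=table_a.df.index,
    )
    df["delta"] = df["z_y"] - df["z_x"]
    return ContrastComparison(
        name_x=table_a.name or "x",
        name_y=table_b.name or "y",
        df=df,
        shared_top=shared,
        specific_top_x=[m for m in top_x if m not in set(shared)],
        specific_top_y=[m for m in top_y if m not in set(shared)],
    )


def scatter_data(comparison: ContrastComparison, x_axis: str = "observed_freq") -> pd.DataFrame:
    """Numeric scatter-plot data.

    ``x_axis='observed_freq'`` (default): one 4096-row block per contrast
    with x = per-100-promoter observed frequency and y = z; ``label_flag``
    marks that contrast's top motifs.  ``x_axis='z'``: a single 4096-row
    block with x = z of contrast A and y = z of contrast B; ``label_flag``
    marks motifs in either top set.
    """
    df = comparison.df
    if x_axis == "observed_freq":
        blocks = []
        for name, fx, zx, tx in (
            (comparison.name_x, "freq_x", "z_x", "top_x"),
            (comparison.name_y, "freq_y", "z_y", "top_y"),
        ):
            blocks.append(pd.DataFrame({
                "contrast": name,
                "motif": df.index,
                "x": df[fx].to_numpy(),
                "y": df[zx].to_numpy(),
                "label_flag": df[tx].to_numpy(),
            }))
        return pd.concat(blocks, ignore_index=True)
    if x_axis == "z":
        return pd.DataFrame({
            "contrast": f"{comparison.name_y}_vs_{comparison.name_x}",
            "motif": df.index,
            "x": df["z_x"].to_numpy(),
            "y": df["z_y"].to_numpy(),
            "label_flag": (df["top_x"] | df["top_y"]).to_numpy(),
        })
    raise ValueError(f"x_axis must be 'observed_freq' or 'z', got {x_axis!r}")


def plot_scatter(comparison: ContrastComparison, path: str | Path,
                 x_axis: str = "z") -> None:
    """Render the labeled scatter (SVG/PNG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = scatter_data(comparison, x_axis=x_axis)
    fig, ax = plt.subplots(figsize=(6, 6))
    for _, block in data.groupby("contrast"):
        ax.scatter(block["x"], block["y"], s=6, c="0.6", alpha=0.5)
        hits = block[block["label_flag"]]
        ax.scatter(hits["x"], hits["y"], s=18, c="red")
        for r in hits.itertuples(index=False):
            if np.isfinite(r.x) and np.isfinite(r.y):
                ax.annotate(r.motif, (r.x, r.y), fontsize=6, color="red")
    if x_axis == "z":
        ax.set_xlabel(f"Z ({comparison.name_x})")
        ax.set_ylabel(f"Z ({comparison.name_y})")
    else:
        ax.set_xlabel("observed frequency per 100 promoters")
        ax.set_ylabel("Z")
    ax.set_title(f"{comparison.name_y} vs {comparison.name_x}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
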