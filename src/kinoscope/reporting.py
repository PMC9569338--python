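"""Figures and run manifests.

Every figure writes the numeric table behind it next to the image
(figure-from-table discipline), so plots can be audited and regenerated.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from kinoscope import __version__
from kinoscope.errors import ValidationError
from kinoscope.io import write_table
from kinoscope.preprocess import SignalMatrix


def _leaf_order(mat: np.ndarray, linkage: str, metric: str) -> np.ndarray:
    d = pdist(mat, metric=metric)
    return np.asarray(hierarchy.leaves_list(hierarchy.linkage(d, method=linkage)))


def heatmap(
    matrix: SignalMatrix | pd.DataFrame,
    path,
    linkage: str = "complete",
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Clustered heatmap of per-peptide Z scores.

    Rows and columns are ordered by agglomerative clustering (deterministic
    given fixed input). A constant matrix is drawn unclustered with a warning.
    Returns the reordered matrix, which is also written as ``<path>.tsv``.
    """
    z = matrix.zscore if isinstance(matrix, SignalMatrix) else matrix
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValidationError("heatmap needs at least 2 rows and 2 columns")
    vals = z.to_numpy(dtype=float)
    if np.allclose(vals, vals.flat[0]):
        warnings.warn("constant matrix; clustering skipped", stacklevel=2)
        ordered = z
    else:
        rows = _leaf_order(vals, linkage, metric)
        cols = _leaf_order(vals.T, linkage, metric)
        ordered = z.iloc[rows, cols]

    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * ordered.shape[1] + 2), max(4, 0.06 * ordered.shape[0] + 2))
    )
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_xticks(range(ordered.shape[1]))
    labels = [":".join(map(str, c)) if isinstance(c, tuple) else str(c) for c in ordered.columns]
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{ordered.shape[0]} peptides")
    fig.colorbar(im, ax=ax, label="Z score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    flat = ordered.copy()
    flat.columns = labels
    write_table(flat.reset_index(), str(path) + ".tsv")
    return ordered


def waterfall(lfc: pd.DataFrame, path, display_cutoff: float = 0.2) -> pd.DataFrame:
    """Waterfall of per-peptide log2 fold-changes.

    Peptides are sorted by mean log2FC; each chip is a small point and the
    replicate mean a large point, colored by |mean| versus ``display_cutoff``.
    Returns the sorted table (also written as ``<path>.tsv``).
    """
    chip_cols = [c for c in lfc.columns if c.startswith("log2fc_")]
    df = lfc.sort_values("mean_log2fc", kind="mergesort").reset_index(drop=True)
    y = np.arange(len(df))
    colors = np.where(
        df["mean_log2fc"] > display_cutoff,
        "tab:red",
        np.where(df["mean_log2fc"] < -display_cutoff, "tab:blue", "grey"),
    )
    fig, ax = plt.subplots(figsize=(6, max(4, 0.05 * len(df) + 2)))
    for c in chip_cols:
        ax.scatter(df[c], y, s=6, color="lightgrey", zorder=1)
    ax.scatter(df["mean_log2fc"], y, s=20, c=colors, zorder=2)
    ax.axvline(0, color="black", lw=0.5)
    for cut in (display_cutoff, -display_cutoff):
        ax.axvline(cut, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("log2 fold-change")
    ax.set_ylabel("peptides (sorted by mean log2FC)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    write_table(df, str(path) + ".tsv")
    return df


def kinetic_curves(series: pd.DataFrame, peptides: list[str], path) -> pd.DataFrame:
    """Mean intensity versus exposure time per group for selected peptides."""
    if not peptides:
        raise ValidationError("empty peptide selection")
    unknown = sorted(set(peptides) - set(series["peptide_id"]))
    if unknown:
        raise ValidationError(f"unknown peptide(s): {unknown[:5]}")
    sub = series[series["peptide_id"].isin(peptides)]
    curves = (
        sub.groupby(["peptide_id", "group", "exposure_ms"])["intensity"]
        .mean()
        .rename("mean_intensity")
        .reset_index()
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    for (pep, group), cd in curves.groupby(["peptide_id", "group"]):
        cd = cd.sort_values("exposure_ms")
        ax.plot(cd["exposure_ms"], cd["mean_intensity"], marker="o", ms=3, label=f"{pep} ({group})")
    ax.set_xlabel("exposure time (ms)")
    ax.set_ylabel("intensity (chip mean)")
    if len(peptides) * series["group"].nunique() <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    write_table(curves, str(path) + ".tsv")
    return curves


def violin(matrix: SignalMatrix, path, kind: str = "violin") -> pd.DataFrame:
    """Per-group distribution of per-peptide mean signals (violin or box)."""
    lvl0 = matrix.log2.columns.get_level_values(0)
    groups = sorted(set(lvl0))
    data = [matrix.log2.loc[:, lvl0 == g].mean(axis=1).to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    if kind == "violin":
        ax.violinplot(data, showmedians=True)
    else:
        ax.boxplot(data)
    ax.set_xticks(range(1, len(groups) + 1))
    ax.set_xticklabels(groups, rotation=45, ha="right")
    ax.set_ylabel("mean log2 signal per peptide")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    table = pd.DataFrame({g: d for g, d in zip(groups, data)}, index=matrix.log2.index)
    write_table(table.reset_index(), str(path) + ".tsv")
    return table


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(run_dir, config: dict | None = None, seeds: dict | None = None) -> dict:
    """Record config, seeds, software version and a digest + row count for
    every table in ``run_dir`` as ``manifest.json``."""
    run_dir = Path(run_dir)
    outputs = {}
    for f in sorted(run_dir.glob("*.tsv")):
        with open(f) as fh:
            n_rows = max(sum(1 for _ in fh) - 1, 0)
        outputs[f.name] = {"sha256": file_digest(f), "n_rows": n_rows}
    manifest = {
        "kinoscope_version": __version__,
        "config": config or {},
        "seeds": seeds or {},
        "outputs": outputs,
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
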