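"""Figure-style views of activation tables and comparison results.

Every plot is a derived view of a table that is also written as TSV;
plots are never the only record of a number.  All functions return the
matplotlib Figure so callers control saving (SVG primary).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless; must precede pyplot import

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .compare import PCAResult, RegressionResult
from .genesets import FactorList, GeneSetCollection
from .io import PerturbationMatrix
from .scoring import ActivationResults


def plot_heatmap(
    m: PerturbationMatrix,
    collection: GeneSetCollection,
    factor_list: FactorList | None = None,
    vmax: float = 3.0,
    ax=None,
):
    """Target-gene × perturbation heatmap, diverging scale centered at 0.

    Rows are the pathway sets' genes in set-file order (pathway by
    pathway); columns are perturbations, grouped by the factor list's
    sublists when one is given.
    """
    row_genes: list[str] = []
    row_labels: list[str] = []
    panel = set(m.genes)
    for name, s in collection.pathway_sets.items():
        for g in s.genes:
            if g in panel and g not in row_genes:
                row_genes.append(g)
                row_labels.append(name)
    if not row_genes:
        raise ValueError("no pathway genes present in the matrix panel")

    perts = list(m.perturbations)
    if factor_list is not None:
        order = {g: i for i, g in enumerate(factor_list.members)}
        perts = sorted(
            [
                p
                for p in perts
                if m.pert_meta.at[p, "target_gene"] in order
            ],
            key=lambda p: order[m.pert_meta.at[p, "target_gene"]],
        )
        if not perts:
            raise ValueError("no perturbations target the factor list")

    data = pd.DataFrame(
        m.z[np.ix_([m.pert_index(p) for p in perts], m.gene_index(row_genes))].T,
        index=row_genes,
        columns=perts,
    )
    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(4, 0.25 * len(perts)), max(3, 0.18 * len(row_genes)))
        )
    sns.heatmap(
        data, cmap="RdBu_r", center=0.0, vmin=-vmax, vmax=vmax,
        cbar_kws={"label": "z-score"}, ax=ax,
    )
    ax.set_xlabel("perturbation")
    ax.set_ylabel("target gene (grouped by pathway)")
    return ax.figure


def plot_volcano(results: ActivationResults, ax=None):
    """Activation score vs −log10 p, one series per pathway.

    p = 1 rows sit at y = 0; a dashed line marks the configured α.
    """
    t = results.table
    if not len(t):
        raise ValueError("empty activation table")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    y = np.where(np.isfinite(t["neg_log10_p"]), t["neg_log10_p"], 320.0)
    for name, grp in t.groupby("pathway", sort=False):
        ax.scatter(
            grp["score"], y[t["pathway"] == name], s=12, alpha=0.7, label=name
        )
    ax.axhline(-np.log10(results.alpha), ls="--", c="grey", lw=1)
    ax.set_xlabel("pathway activation score (mean z)")
    ax.set_ylabel("-log10 p (Welch vs control set)")
    ax.legend(title="pathway", fontsize=8)
    return ax.figure


def plot_regression(m: PerturbationMatrix, result: RegressionResult,
                    genes: list[str], ax=None):
    """Scatter of the filtered genes with the fitted line and R²."""
    x = m.profile(result.pert_x)[genes] if result.pert_x in m.perturbations else None
    y = m.profile(result.pert_y)[genes] if result.pert_y in m.perturbations else None
    if x is None or y is None:
        raise ValueError("plot_regression needs perturbation ids in the matrix")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=10, alpha=0.6)
    if result.defined:
        xs = np.linspace(float(x.min()), float(x.max()), 50)
        ax.plot(xs, result.intercept + result.slope * xs, c="crimson", lw=1.5)
        ax.set_title(f"R² = {result.r2:.3f} (n = {result.n_genes})")
    ax.set_xlabel(f"{result.pert_x} z-score")
    ax.set_ylabel(f"{result.pert_y} z-score")
    return ax.figure


def plot_pca(result: PCAResult, color_by: pd.Series | None = None, ax=None):
    """PC1 vs PC2 scores with axis labels carrying variance fractions."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    scores = result.component_scores
    if color_by is not None:
        for label, grp in scores.groupby(color_by.reindex(scores.index)):
            ax.scatter(grp["PC1"], grp["PC2"], s=14, alpha=0.8, label=str(label))
        ax.legend(fontsize=8)
    else:
        ax.scatter(scores["PC1"], scores["PC2"], s=14, alpha=0.8)
    vf = result.variance_fractions
    ax.set_xlabel(f"PC1 ({100 * vf[0]:.1f}% of variance)")
    ax.set_ylabel(f"PC2 ({100 * vf[1]:.1f}% of variance)")
    return ax.figure
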