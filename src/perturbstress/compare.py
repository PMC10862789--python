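"""Transcriptome-wide perturbation-pair comparison and PCA.

Two perturbations that activate the same stress program produce
correlated transcriptome-wide z-score profiles.  This module quantifies
that with simple linear regression over the genes that respond to
either perturbation (|z| strictly greater than a cutoff, 0.5 by
default, in either profile — the union rule), summarises gene classes
(e.g. mtDNA-encoded genes) separately, and runs PCA over groups of
perturbation profiles.

Grouped comparisons average member perturbations gene-wise into one
synthetic profile before filtering and regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from .io import PerturbationMatrix

DEFAULT_Z_THRESHOLD = 0.5


def _profile(m: PerturbationMatrix, pert) -> pd.Series:
    """Resolve a perturbation id or a precomputed profile Series."""
    if isinstance(pert, pd.Series):
        return pert
    return m.profile(pert)


def filter_by_z(
    m: PerturbationMatrix,
    pert_a,
    pert_b,
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> list[str]:
    """Genes responding to either perturbation: |z| > threshold (strict).

    The union rule over the two profiles; gene order follows the matrix
    panel.  Antitone in the threshold: raising the cutoff never adds a
    gene.  An empty result is allowed.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    a = _profile(m, pert_a)
    b = _profile(m, pert_b)
    mask = (a.abs() > threshold) | (b.abs() > threshold)
    return list(a.index[mask])


@dataclass
class RegressionResult:
    """Simple linear fit of one perturbation's profile on another's.

    ``r2`` is the coefficient of determination of the OLS fit over
    ``n_genes`` filtered genes; it equals the squared Pearson r and is
    symmetric in the pair.  ``defined`` is False when the explanatory
    profile has zero variance over the filtered genes.
    """

    pert_x: str
    pert_y: str
    slope: float
    intercept: float
    r2: float
    n_genes: int
    threshold: float | None
    defined: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def regress(
    m: PerturbationMatrix,
    pert_x,
    pert_y,
    genes: list[str] | None = None,
    threshold: float | None = DEFAULT_Z_THRESHOLD,
) -> RegressionResult:
    """OLS of *pert_y*'s z on *pert_x*'s z over responsive genes.

    When *genes* is None the gene list comes from :func:`filter_by_z` at
    *threshold* (pass ``threshold=None`` to use all genes).  Either
    argument may be a perturbation id or a profile Series (e.g. from
    :func:`group_profile`).  A zero-variance x or fewer than 2 genes
    yields a flagged, NaN-valued result rather than an exception.
    """
    x = _profile(m, pert_x)
    y = _profile(m, pert_y)
    if genes is None:
        genes = (
            filter_by_z(m, x, y, threshold) if threshold is not None else list(x.index)
        )
    xv = x[genes].to_numpy(dtype=float)
    yv = y[genes].to_numpy(dtype=float)
    name_x = str(x.name) if x.name is not None else "x"
    name_y = str(y.name) if y.name is not None else "y"
    if len(genes) < 2 or np.var(xv) == 0.0:
        return RegressionResult(
            name_x, name_y, np.nan, np.nan, np.nan,
            n_genes=len(genes), threshold=threshold, defined=False,
        )
    fit = stats.linregress(xv, yv)
    return RegressionResult(
        pert_x=name_x,
        pert_y=name_y,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        n_genes=len(genes),
        threshold=threshold,
    )


def group_profile(
    m: PerturbationMatrix, perts: list[str], name: str | None = None
) -> pd.Series:
    """Per-gene mean z across a group of perturbations.

    Returns a Series usable wherever a perturbation id is accepted
    (e.g. as one side of :func:`regress`).
    """
    if not perts:
        raise ValueError("empty perturbation group")
    idx = [m.pert_index(p) for p in perts]
    mean = m.z[idx].mean(axis=0)
    return pd.Series(mean, index=m.genes, name=name or "+".join(map(str, perts)))


@dataclass
class GeneClassContrast:
    """Within/outside-class mean z per perturbation plus the cross contrast.

    ``difference`` is (pert_a − pert_b) mean z within the class — e.g.
    how much lower mtDNA-encoded genes sit in one knockdown than the
    other.
    """

    class_flag: str
    n_class_genes: int
    per_perturbation: pd.DataFrame  # index pert, cols mean_in_class / mean_outside
    difference: float


def compare_gene_class(
    m: PerturbationMatrix, pert_a, pert_b, class_flag: str = "mtdna_encoded"
) -> GeneClassContrast:
    """Contrast a flagged gene class between two perturbations.

    Raises if *class_flag* is not annotated (naming available flags) or
    flags no genes.
    """
    if class_flag not in m.gene_meta.columns:
        raise KeyError(
            f"gene class {class_flag!r} not annotated; available: "
            f"{list(m.gene_meta.columns)}"
        )
    mask = m.gene_meta[class_flag].to_numpy(dtype=bool)
    if not mask.any():
        raise ValueError(f"gene class {class_flag!r} flags no genes in the panel")
    rows = {}
    for p in (pert_a, pert_b):
        prof = _profile(m, p)
        vals = prof.to_numpy(dtype=float)
        rows[str(prof.name)] = {
            "mean_in_class": float(vals[mask].mean()),
            "mean_outside": float(vals[~mask].mean()) if (~mask).any() else np.nan,
        }
    per_pert = pd.DataFrame(rows).T
    diff = float(
        per_pert["mean_in_class"].iloc[0] - per_pert["mean_in_class"].iloc[1]
    )
    return GeneClassContrast(
        class_flag=class_flag,
        n_class_genes=int(mask.sum()),
        per_perturbation=per_pert,
        difference=diff,
    )


@dataclass
class PCAResult:
    """Principal components of perturbation profiles.

    ``component_scores``: perturbation × component; ``loadings``: gene ×
    component; ``variance_fractions``: non-negative, non-increasing,
    summing to 1.  Components are deterministic up to sign.  ``defined``
    is False for a constant input matrix.
    """

    component_scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fractions: np.ndarray
    centered: bool
    scaled: bool
    defined: bool = True


def pca(
    m: PerturbationMatrix,
    perts: list[str] | None = None,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """PCA of the perturbation × gene z matrix (observations = perturbations).

    Defaults mirror R's ``prcomp``: genes centered, not scaled.  With
    ``scale=True`` genes are divided by their SD (constant genes are
    left unscaled).  A constant matrix yields a flagged result with NaN
    variance fractions.
    """
    if perts is None:
        perts = list(m.perturbations)
    if len(perts) < 2 or len(m.genes) < 2:
        raise ValueError("PCA needs >= 2 perturbations and >= 2 genes")
    idx = [m.pert_index(p) for p in perts]
    X = m.z[idx].astype(float).copy()
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0.0] = 1.0
        X = X / sd

    k = min(len(perts), len(m.genes))
    if np.allclose(X - X.mean(axis=0), 0.0):
        comps = [f"PC{i + 1}" for i in range(k)]
        return PCAResult(
            component_scores=pd.DataFrame(np.nan, index=perts, columns=comps),
            loadings=pd.DataFrame(np.nan, index=m.genes, columns=comps),
            variance_fractions=np.full(k, np.nan),
            centered=center, scaled=scale, defined=False,
        )

    # sklearn always centers; for center=False add the mean offset back in
    # via an uncentered SVD.
    if center:
        model = _SKPCA(n_components=k, svd_solver="full")
        scores = model.fit_transform(X)
        loadings = model.components_.T
        fractions = model.explained_variance_ratio_
    else:
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        scores = U * S
        loadings = Vt.T
        fractions = S**2 / np.sum(S**2)
    comps = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        component_scores=pd.DataFrame(scores, index=perts, columns=comps),
        loadings=pd.DataFrame(loadings, index=m.genes, columns=comps),
        variance_fractions=np.asarray(fractions, dtype=float),
        centered=center,
        scaled=scale,
    )
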