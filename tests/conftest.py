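"""Shared fixtures and independent statistical oracles.

The oracle functions implement the textbook formulas directly (Welch's
t with Welch–Satterthwaite degrees of freedom, Welch's 1951 k-group
ANOVA, the Brown-Forsythe median-centered Levene statistic, OLS via the
normal equations) so that the package's library-backed implementations
are checked against an independent route.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perturbstress import (
    GeneSetCollection,
    PerturbationMatrix,
    default_spec,
    load_stress_panels,
    simulate_study,
)

# ---------------------------------------------------------------------------
# Oracles (textbook formulas, independent of the implementation path)
# ---------------------------------------------------------------------------


def oracle_welch_t(a, b) -> tuple[float, float]:
    """Welch's t statistic and two-sided p with Welch–Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def oracle_welch_anova(groups) -> tuple[float, float]:
    """Welch's (1951) k-group ANOVA F statistic and p-value."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    W = w.sum()
    grand = (w * m).sum() / W
    A = (w * (m - grand) ** 2).sum() / (k - 1)
    lam = ((1 - w / W) ** 2 / (n - 1)).sum()
    B = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    F = A / B
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * lam)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), p


def oracle_brown_forsythe(groups) -> tuple[float, float]:
    """Brown-Forsythe: one-way ANOVA on |x − group median|."""
    devs = [np.abs(np.asarray(g, float) - np.median(g)) for g in groups]
    k = len(devs)
    n = np.array([len(d) for d in devs], float)
    N = n.sum()
    means = np.array([d.mean() for d in devs])
    grand = np.concatenate(devs).mean()
    ss_between = (n * (means - grand) ** 2).sum()
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in devs)
    F = (ss_between / (k - 1)) / (ss_within / (N - k))
    p = float(stats.f.sf(F, k - 1, N - k))
    return float(F), p


def oracle_ols(x, y) -> tuple[float, float, float]:
    """Slope, intercept, R² from the normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    yhat = X @ beta
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return float(beta[1]), float(beta[0]), float(1 - ss_res / ss_tot)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def panels() -> GeneSetCollection:
    return load_stress_panels()


@pytest.fixture(scope="session")
def study_panels(panels) -> GeneSetCollection:
    """The four-pathway collection used by the default synthetic study."""
    return panels.subset(["ISR", "UPR", "HSR", "OSR"])


def make_matrix(z, genes=None, perts=None, **kwargs) -> PerturbationMatrix:
    z = np.asarray(z, float)
    genes = genes or [f"G{j}" for j in range(z.shape[1])]
    perts = perts or [f"P{i}" for i in range(z.shape[0])]
    return PerturbationMatrix(genes=genes, perturbations=perts, z=z, **kwargs)


@pytest.fixture
def toy_matrix() -> PerturbationMatrix:
    """4 perturbations × 6 genes with hand-checkable values."""
    z = np.array(
        [
            [0.6, 0.4, -0.7, 0.0, 0.5, -0.5],
            [0.0, 0.0, 0.0, 0.9, 0.0, 0.0],
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        ]
    )
    return make_matrix(z, genes=[f"G{j}" for j in range(6)])


@pytest.fixture(scope="session")
def small_study():
    """Small default-structure synthetic study shared across tests."""
    spec = default_spec(seed=20, n_per_class=8, n_null=16, n_genes=400)
    matrix, truth = simulate_study(spec)
    return spec, matrix, truth.set_index("perturbation")
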