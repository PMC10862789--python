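"""Pathway activation scoring and significance testing.

The activation score of a stress pathway in one perturbation is the
arithmetic mean of the z-scores of the pathway's target genes.  Its
significance is assessed against the control gene set for the same
perturbation with two unequal-variance tests:

* Welch's t-test (two-group) / Welch ANOVA (k-group) on the means —
  "is the pathway's average expression shifted relative to the control
  genes?"
* the Brown-Forsythe test (median-centered Levene) on the spreads —
  "is the pathway's dispersion different from the control genes'?"

The two-group Welch test drives volcano-style tables
(:class:`PathwayActivation` / :class:`ActivationResults`); the k-group
Welch ANOVA with Games–Howell post hoc comparisons
(:func:`omnibus_test`) backs multi-pathway bar panels.

Degenerate inputs follow fixed conventions so that batch runs over
thousands of perturbations never abort: when both groups are constant,
p = 1 if they are equal and p = 0 otherwise (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, GeneSetCollection, map_to_panel
from .io import PerturbationMatrix

logger = logging.getLogger(__name__)

#: Asterisk tiers used in figure-style annotations.
SIGNIFICANCE_TIERS = (0.05, 0.01, 0.005)

ACTIVATION_COLUMNS = (
    "perturbation",
    "target_gene",
    "pathway",
    "score",
    "n_genes_used",
    "p_value",
    "bf_p_value",
    "neg_log10_p",
    "significant",
)


# ---------------------------------------------------------------------------
# Elementary statistics with degenerate-input conventions
# ---------------------------------------------------------------------------


def _degenerate_p(a: np.ndarray, b: np.ndarray) -> float:
    """Convention for two constant groups: 1 if equal, else 0."""
    p = 1.0 if float(a[0]) == float(b[0]) else 0.0
    logger.debug("degenerate two-constant-group comparison: p = %g", p)
    return p


def welch_t_pvalue(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch unequal-variance t-test p-value.

    Zero-variance groups follow the module's degenerate conventions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return _degenerate_p(a, b)
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def brown_forsythe_pvalue(*groups: Sequence[float]) -> float:
    """Brown-Forsythe (median-centered Levene) p-value across groups.

    The statistic is an ANOVA on absolute deviations from each group's
    median; when those deviations are constant in every group the
    statistic is undefined and the convention is p = 1 if the deviation
    levels agree, else 0.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    devs = [np.abs(g - np.median(g)) for g in arrs]
    if all(d.var(ddof=1) == 0.0 for d in devs):
        levels = [float(d[0]) for d in devs]
        p = 1.0 if len(set(levels)) == 1 else 0.0
        logger.debug("degenerate Brown-Forsythe: p = %g", p)
        return p
    return float(stats.levene(*arrs, center="median").pvalue)


def welch_anova_pvalue(groups: dict[str, Sequence[float]]) -> tuple[float, float]:
    """k-group Welch ANOVA (F, p) across named groups of z-values.

    Constant identical groups return (0, 1) by convention.
    """
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if all(a.var(ddof=1) == 0.0 for a in arrs.values()):
        means = {float(a[0]) for a in arrs.values()}
        return (0.0, 1.0) if len(means) == 1 else (np.inf, 0.0)
    long = pd.DataFrame(
        {
            "z": np.concatenate(list(arrs.values())),
            "group": np.repeat(list(arrs), [len(a) for a in arrs.values()]),
        }
    )
    aov = pg.welch_anova(data=long, dv="z", between="group")
    return float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0])


# ---------------------------------------------------------------------------
# Scores and per-perturbation tests
# ---------------------------------------------------------------------------


def activation_score(m: PerturbationMatrix, gene_set: GeneSet, pert: str) -> float:
    """Mean z-score of the set's genes in one perturbation.

    Deterministic and independent of gene order and of genes outside
    the set; adding δ to every set gene's z raises the score by exactly δ.
    """
    return float(np.mean(m.set_values(pert, gene_set.genes)))


def pathway_pvalue(
    m: PerturbationMatrix,
    gene_set: GeneSet,
    control_set: GeneSet,
    pert: str,
) -> tuple[float, float]:
    """(Welch p, Brown-Forsythe p) of pathway vs control z-values.

    Both sets must carry at least 2 mapped genes.
    """
    if len(gene_set) < 2 or len(control_set) < 2:
        raise ValueError("both gene sets need >= 2 mapped genes for testing")
    a = m.set_values(pert, gene_set.genes)
    b = m.set_values(pert, control_set.genes)
    return welch_t_pvalue(a, b), brown_forsythe_pvalue(a, b)


@dataclass
class OmnibusResult:
    """k-group comparison of all pathway sets (plus control) in one perturbation."""

    perturbation: str
    welch_f: float
    welch_anova_p: float
    brown_forsythe_p: float
    posthoc: pd.DataFrame  # Games-Howell, pathway-vs-control rows flagged


def omnibus_test(
    m: PerturbationMatrix, collection: GeneSetCollection, pert: str
) -> OmnibusResult:
    """Welch ANOVA + Brown-Forsythe across all sets, Games–Howell post hoc.

    The post hoc table contains every pairwise comparison; the
    ``vs_control`` column marks the pathway-vs-control contrasts that
    figure-style bar panels annotate.
    """
    groups = {
        name: m.set_values(pert, s.genes) for name, s in collection.sets.items()
    }
    if len(groups) < 2:
        raise ValueError("omnibus test needs >= 2 gene sets")
    f, welch_p = welch_anova_pvalue(groups)
    bf_p = brown_forsythe_pvalue(*groups.values())

    long = pd.DataFrame(
        {
            "z": np.concatenate(list(groups.values())),
            "group": np.repeat(list(groups), [len(v) for v in groups.values()]),
        }
    )
    if all(np.var(v, ddof=1) == 0.0 for v in groups.values()):
        posthoc = pd.DataFrame(columns=["A", "B", "pval", "vs_control"])
    else:
        posthoc = pg.pairwise_gameshowell(data=long, dv="z", between="group")
        control = collection.control_name
        posthoc["vs_control"] = (posthoc["A"] == control) | (
            posthoc["B"] == control
        )
    return OmnibusResult(
        perturbation=str(pert),
        welch_f=f,
        welch_anova_p=welch_p,
        brown_forsythe_p=bf_p,
        posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class PathwayActivation:
    """Pathway-activation model over a pseudobulk z-score matrix.

    Built from a :class:`~perturbstress.io.PerturbationMatrix` and a
    :class:`~perturbstress.genesets.GeneSetCollection`; :meth:`fit`
    computes one activation score and significance call per
    (perturbation, pathway) pair and returns an
    :class:`ActivationResults`.

    Parameters
    ----------
    matrix : PerturbationMatrix
    collection : GeneSetCollection
        Mapped to the matrix panel on construction; sets with coverage
        below *min_fraction* are flagged (logged) but still scored.
    alpha : float
        Significance level for the ``significant`` call (default 0.05).
    adjust : {None, 'fdr_bh'}
        Multiple-testing adjustment applied across perturbations within
        each pathway.  Default None, i.e. raw per-test p-values.
    """

    def __init__(
        self,
        matrix: PerturbationMatrix,
        collection: GeneSetCollection,
        alpha: float = 0.05,
        adjust: str | None = None,
        min_fraction: float = 0.5,
    ) -> None:
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        if adjust not in (None, "fdr_bh"):
            raise ValueError(f"unknown adjustment {adjust!r}")
        self.matrix = matrix
        self.collection, self.coverage = map_to_panel(
            collection, matrix.genes, min_fraction=min_fraction
        )
        self.alpha = alpha
        self.adjust = adjust

    def fit(self, perturbations: Iterable[str] | None = None) -> "ActivationResults":
        """Score every (perturbation, pathway) pair and test vs control.

        Per-row failures are logged and the batch continues; failed rows
        are absent from the table.
        """
        perts = (
            list(self.matrix.perturbations)
            if perturbations is None
            else [str(p) for p in perturbations]
        )
        unknown = [p for p in perts if p not in set(self.matrix.perturbations)]
        if unknown:
            raise KeyError(f"perturbations not in matrix: {unknown[:5]}")

        control = self.collection.control
        rows = []
        for pert in perts:
            target = self.matrix.pert_meta.at[pert, "target_gene"]
            for name, s in self.collection.pathway_sets.items():
                try:
                    score = activation_score(self.matrix, s, pert)
                    p, bf_p = pathway_pvalue(self.matrix, s, control, pert)
                except Exception:
                    logger.exception(
                        "scoring failed for (%s, %s); continuing batch", pert, name
                    )
                    continue
                rows.append(
                    {
                        "perturbation": pert,
                        "target_gene": target,
                        "pathway": name,
                        "score": score,
                        "n_genes_used": len(s),
                        "p_value": p,
                        "bf_p_value": bf_p,
                    }
                )
        table = pd.DataFrame(rows, columns=list(ACTIVATION_COLUMNS[:7]))

        if len(table):
            if self.adjust == "fdr_bh":
                adjusted = np.empty(len(table))
                for _, idx in table.groupby("pathway").groups.items():
                    adjusted[table.index.get_indexer(idx)] = multipletests(
                        table.loc[idx, "p_value"], method="fdr_bh"
                    )[1]
                table["p_adjusted"] = adjusted
            sig_p = table["p_adjusted"] if self.adjust else table["p_value"]
            with np.errstate(divide="ignore"):
                table["neg_log10_p"] = np.where(
                    table["p_value"] > 0, -np.log10(table["p_value"]), np.inf
                )
            table["significant"] = sig_p < self.alpha
        else:
            table["neg_log10_p"] = pd.Series(dtype=float)
            table["significant"] = pd.Series(dtype=bool)
        ordered = [c for c in ACTIVATION_COLUMNS if c in table.columns]
        extra = [c for c in table.columns if c not in ordered]
        return ActivationResults(self, table[ordered + extra])


class ActivationResults:
    """Fitted activation scores with significance calls.

    ``table`` has one row per (perturbation, pathway) with the fixed
    column order ``perturbation, target_gene, pathway, score,
    n_genes_used, p_value, bf_p_value, neg_log10_p, significant`` — the
    substrate of volcano plots.
    """

    def __init__(self, model: PathwayActivation, table: pd.DataFrame) -> None:
        self.model = model
        self.table = table
        self.alpha = model.alpha
        self.adjust = model.adjust

    def __len__(self) -> int:
        return len(self.table)

    def stars(self) -> pd.Series:
        """Figure-style asterisk tiers from the Welch p-value."""
        p = self.table["p_value"]
        tiers = sorted(SIGNIFICANCE_TIERS, reverse=True)  # 0.05, 0.01, 0.005
        stars = pd.Series("", index=self.table.index, dtype=object)
        for i, tier in enumerate(tiers, start=1):
            stars[p < tier] = "*" * i
        return stars

    def summary(self) -> str:
        """Human-readable per-pathway significance summary."""
        lines = [
            "Pathway activation results",
            "==========================",
            f"perturbations: {self.table['perturbation'].nunique()}",
            f"pathways:      {self.table['pathway'].nunique()}",
            f"alpha:         {self.alpha}   adjustment: {self.adjust or 'none'}",
            "",
            f"{'pathway':<14}{'n':>6}{'n significant':>15}{'mean score':>13}",
        ]
        for name, grp in self.table.groupby("pathway", sort=False):
            lines.append(
                f"{name:<14}{len(grp):>6}{int(grp['significant'].sum()):>15}"
                f"{grp['score'].mean():>13.3f}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def correlate_knockdown(self) -> pd.DataFrame:
        """Per-pathway Pearson correlation of score vs knockdown fraction.

        Perturbations lacking a knockdown fraction are excluded (count
        logged).  Fewer than 3 usable pairs, or zero variance on either
        axis, marks the pathway's row undefined rather than raising.
        """
        kd = self.model.matrix.pert_meta["knockdown_fraction"]
        rows = []
        for name, grp in self.table.groupby("pathway", sort=False):
            merged = pd.DataFrame(
                {
                    "score": grp.set_index("perturbation")["score"],
                    "kd": kd.reindex(grp["perturbation"]),
                }
            ).dropna()
            n_dropped = len(grp) - len(merged)
            if n_dropped:
                logger.info(
                    "pathway %s: %d perturbations without knockdown fraction",
                    name, n_dropped,
                )
            if (
                len(merged) < 3
                or merged["score"].nunique() == 1
                or merged["kd"].nunique() == 1
            ):
                rows.append(
                    {"pathway": name, "r": np.nan, "p_value": np.nan,
                     "n": len(merged), "undefined": True}
                )
                continue
            r, p = stats.pearsonr(merged["score"], merged["kd"])
            rows.append(
                {"pathway": name, "r": float(r), "p_value": float(p),
                 "n": len(merged), "undefined": False}
            )
        return pd.DataFrame(rows).set_index("pathway")
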