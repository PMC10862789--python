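"""Synthetic pseudobulk Perturb-seq study generator with ground truth.

Emulates the statistical structure the analysis assumes: raw per-gene
expression for perturbation and control sgRNAs across 10X gemgroups,
z-normalization of every sgRNA against the control sgRNAs of its own
gemgroup, class-structured perturbations carrying planted mean shifts
(δ, on the z scale) on pathway gene sets, an optional down-shift of
mtDNA-encoded genes, and Beta-distributed knockdown-fraction metadata
drawn independently of effect size.

The default study mirrors the qualitative selectivity patterns of
organelle-specific proteostasis disruption:

* ``mito_like``   — ISR δ = 1.5, mtDNA-encoded genes shifted −0.8
* ``er_like``     — UPR δ = 1.5 with a weaker ISR δ = 0.5 (PERK arm)
* ``keap1_like``  — OSR δ = 1.5
* ``uba1_like``   — HSR δ = 1.5
* ``eif2b_like``  — ISR δ = 1.5 through a non-mitochondrial mechanism
* ``null``        — no planted program

All randomness flows from a single :class:`numpy.random.Generator`
seeded from the spec, drawn in a fixed order, so output is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection, load_stress_panels
from .io import PerturbationMatrix

#: The 13 protein-coding genes of the human mitochondrial genome.
MTDNA_GENES = (
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
)

#: Target-gene pools used to name each class's perturbations.
CLASS_TARGET_POOLS: dict[str, tuple[str, ...]] = {
    "mito_like": (
        "HSPA9", "HSPE1", "HSPD1", "LONP1", "CLPP", "CLPX", "AFG3L2",
        "TIMM23B", "TIMM17A", "TIMM44", "TOMM22", "TOMM40", "PAM16", "PHB2",
    ),
    "er_like": (
        "HSPA5", "DDOST", "DAD1", "SRP68", "SRP72", "RPN1", "STT3A",
        "SEC61A1", "SYVN1", "CANX",
    ),
    "keap1_like": ("KEAP1",),
    "uba1_like": ("UBA1",),
    "eif2b_like": ("EIF2B1", "EIF2B2", "EIF2B3", "EIF2B4", "EIF2B5"),
    "null": ("NEG",),
}


@dataclass(frozen=True)
class PerturbationProgram:
    """Planted transcriptional program for one perturbation class.

    ``shifts`` maps gene-set names to the mean z shift δ planted on the
    set's member genes; an empty mapping is the null class.
    ``mtdna_shift`` additionally shifts mtDNA-encoded genes.
    Knockdown fractions are Beta(a, b) draws independent of δ, so the
    score-vs-knockdown correlation has a true null.
    """

    shifts: Mapping[str, float] = field(default_factory=dict)
    mtdna_shift: float | None = None
    knockdown_alpha: float = 6.0
    knockdown_beta: float = 2.0


@dataclass
class SyntheticSpec:
    """Full description of a simulated pseudobulk study.

    Parameters
    ----------
    n_genes : int
        Panel size; gene-set members and the 13 mtDNA genes come first,
        filler genes pad the rest.
    classes : mapping class name -> PerturbationProgram
    n_per_class : mapping class name -> perturbation count
    noise_sd : float
        SD of the per-gene z-scale noise (1 = the null standard normal).
    n_gemgroups, n_controls_per_gemgroup : int
        Normalization strata and control sgRNAs per stratum.
    module_loading : float
        Optional correlated-module mode: loading of a shared latent
        factor added to every gene of each pathway set (0 = independent
        genes, the default noise model).
    seed : int
    """

    n_genes: int = 2000
    classes: dict[str, PerturbationProgram] = field(default_factory=dict)
    n_per_class: dict[str, int] = field(default_factory=dict)
    noise_sd: float = 1.0
    n_gemgroups: int = 4
    n_controls_per_gemgroup: int = 250
    module_loading: float = 0.0
    seed: int = 0
    collection: GeneSetCollection | None = None

    def __post_init__(self) -> None:
        if self.collection is None:
            self.collection = load_stress_panels().subset(
                ["ISR", "UPR", "HSR", "OSR"]
            )
        if set(self.classes) != set(self.n_per_class):
            raise ValueError("classes and n_per_class must list the same classes")
        for cname, prog in self.classes.items():
            for set_name in prog.shifts:
                if set_name not in self.collection.sets:
                    raise ValueError(
                        f"class {cname!r} shifts unknown gene set {set_name!r}"
                    )
        if self.n_controls_per_gemgroup < 2:
            raise ValueError("need >= 2 control sgRNAs per gemgroup")

    @property
    def gene_panel(self) -> list[str]:
        """Panel: all gene-set members, the mtDNA genes, then filler."""
        core = list(self.collection.all_genes) + [
            g for g in MTDNA_GENES if g not in self.collection.all_genes
        ]
        if self.n_genes < len(core):
            raise ValueError(
                f"n_genes={self.n_genes} smaller than the {len(core)} "
                "core panel genes"
            )
        filler = [f"GENE{i:04d}" for i in range(self.n_genes - len(core))]
        return core + filler


def default_spec(seed: int = 0, n_per_class: int = 40, n_null: int = 100,
                 **overrides) -> SyntheticSpec:
    """The default synthetic study (five stress classes plus null)."""
    classes = {
        "mito_like": PerturbationProgram(shifts={"ISR": 1.5}, mtdna_shift=-0.8),
        "er_like": PerturbationProgram(shifts={"UPR": 1.5, "ISR": 0.5}),
        "keap1_like": PerturbationProgram(shifts={"OSR": 1.5}),
        "uba1_like": PerturbationProgram(shifts={"HSR": 1.5}),
        "eif2b_like": PerturbationProgram(shifts={"ISR": 1.5}),
        "null": PerturbationProgram(),
    }
    counts = {c: n_per_class for c in classes}
    counts["null"] = n_null
    return SyntheticSpec(
        classes=classes, n_per_class=counts, seed=seed, **overrides
    )


# ---------------------------------------------------------------------------
# Raw simulation and z-normalization
# ---------------------------------------------------------------------------


@dataclass
class RawStudy:
    """Raw (pre-normalization) expression with gemgroup structure.

    ``expression``: sgRNA × gene table including control sgRNAs;
    ``gemgroup``: per-sgRNA stratum; ``control_ids``: the control
    sgRNAs; ``truth``: planted per-perturbation ground truth.
    """

    expression: pd.DataFrame
    gemgroup: pd.Series
    control_ids: list[str]
    truth: pd.DataFrame
    baseline_loc: np.ndarray
    baseline_scale: np.ndarray


def simulate_raw(spec: SyntheticSpec) -> RawStudy:
    """Simulate raw expression for control and perturbation sgRNAs.

    Per gene g the baseline is loc_g + scale_g·ε with ε standard
    normal; planted effects enter as δ·scale_g so they land as a δ mean
    shift on the z scale after control normalization.  Control sgRNAs
    carry no planted effects.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_panel
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    mt_idx = np.array([gene_pos[g] for g in MTDNA_GENES if g in gene_pos], int)

    # per-gene raw location and scale (arbitrary units)
    baseline_loc = rng.normal(5.0, 2.0, size=n_genes)
    baseline_scale = rng.lognormal(mean=0.0, sigma=0.4, size=n_genes)

    # perturbation roster: class-structured ids cycling the target pools
    pert_ids, pert_class, pert_target = [], [], []
    for cname in spec.classes:
        pool = itertools.cycle(
            CLASS_TARGET_POOLS.get(cname, (cname.upper(),))
        )
        for i in range(spec.n_per_class[cname]):
            target = next(pool)
            pert_ids.append(f"{target}_{cname}_{i:03d}")
            pert_class.append(cname)
            pert_target.append(target)

    control_ids = [
        f"CTRL_g{g}_{i:02d}"
        for g in range(spec.n_gemgroups)
        for i in range(spec.n_controls_per_gemgroup)
    ]
    control_gem = [
        g
        for g in range(spec.n_gemgroups)
        for _ in range(spec.n_controls_per_gemgroup)
    ]
    pert_gem = [i % spec.n_gemgroups for i in range(len(pert_ids))]

    all_ids = control_ids + pert_ids
    gemgroup = pd.Series(control_gem + pert_gem, index=all_ids, name="gemgroup")

    noise = rng.normal(0.0, spec.noise_sd, size=(len(all_ids), n_genes))
    effects = np.zeros((len(all_ids), n_genes))
    truth_rows = []
    n_ctrl = len(control_ids)
    for row, (pid, cname) in enumerate(zip(pert_ids, pert_class), start=n_ctrl):
        prog = spec.classes[cname]
        delta = np.zeros(n_genes)
        for set_name, d in prog.shifts.items():
            idx = [gene_pos[g] for g in spec.collection.sets[set_name].genes]
            delta[idx] += d
        if prog.mtdna_shift is not None:
            delta[mt_idx] += prog.mtdna_shift
        if spec.module_loading:
            for set_name in spec.collection.sets:
                idx = [gene_pos[g] for g in spec.collection.sets[set_name].genes]
                delta[idx] += spec.module_loading * rng.normal()
        effects[row] = delta
        truth_rows.append(
            {
                "perturbation": pid,
                "class": cname,
                "target_gene": pert_target[row - n_ctrl],
                "mtdna_shift": prog.mtdna_shift or 0.0,
                **{f"delta_{s}": prog.shifts.get(s, 0.0)
                   for s in spec.collection.pathway_sets},
            }
        )

    kd = np.full(len(pert_ids), np.nan)
    for i, cname in enumerate(pert_class):
        prog = spec.classes[cname]
        kd[i] = rng.beta(prog.knockdown_alpha, prog.knockdown_beta)
    truth = pd.DataFrame(truth_rows).set_index("perturbation")
    truth["knockdown_fraction"] = kd

    # raw = loc + scale * (noise + planted z-scale effect)
    raw = baseline_loc + baseline_scale * (noise + effects)
    expression = pd.DataFrame(raw, index=all_ids, columns=genes)
    return RawStudy(
        expression=expression,
        gemgroup=gemgroup,
        control_ids=list(control_ids),
        truth=truth,
        baseline_loc=baseline_loc,
        baseline_scale=baseline_scale,
    )


def z_normalize(
    expression: pd.DataFrame,
    control_ids: list[str],
    gemgroup: pd.Series,
    zero_sd: str = "error",
    include_controls: bool = False,
) -> pd.DataFrame:
    """z-normalize every sgRNA against its gemgroup's control sgRNAs.

    Per gene and gemgroup, z = (value − control mean) / control sample
    SD (ddof = 1).  A gene with zero control SD in some gemgroup is
    handled per *zero_sd*: 'error' (default), 'drop' the gene
    everywhere, or 'zero' its z in that gemgroup.

    Applied to the control sgRNAs themselves the transform is exactly
    standardizing: per gene and gemgroup their z has mean 0 and sample
    SD 1.
    """
    control_set = set(control_ids)
    missing = control_set - set(expression.index)
    if missing:
        raise ValueError(f"control ids absent from expression: {sorted(missing)[:5]}")
    out = pd.DataFrame(
        np.nan, index=expression.index, columns=expression.columns
    )
    drop_genes: set[str] = set()
    for g in sorted(gemgroup.unique()):
        ids = gemgroup.index[gemgroup == g]
        ctrl = [i for i in ids if i in control_set]
        if len(ctrl) < 2:
            raise ValueError(f"gemgroup {g} has {len(ctrl)} control sgRNAs (< 2)")
        block = expression.loc[ids]
        mu = expression.loc[ctrl].mean(axis=0)
        sd = expression.loc[ctrl].std(axis=0, ddof=1)
        zero = (sd == 0.0).to_numpy()
        if zero.any():
            bad = list(expression.columns[zero])
            if zero_sd == "error":
                raise ValueError(
                    f"zero control SD in gemgroup {g} for genes {bad[:5]}"
                )
            elif zero_sd == "drop":
                drop_genes.update(bad)
            elif zero_sd != "zero":
                raise ValueError(f"unknown zero_sd policy {zero_sd!r}")
        zb = (block - mu) / sd.replace(0.0, np.nan)
        if zero.any() and zero_sd == "zero":
            zb.iloc[:, np.flatnonzero(zero)] = 0.0
        out.loc[ids] = zb
    if drop_genes:
        out = out.drop(columns=sorted(drop_genes))
    if not include_controls:
        out = out.drop(index=[i for i in expression.index if i in control_set])
    if zero_sd == "drop":
        out = out.dropna(axis=1, how="any")
    return out


def simulate_study(spec: SyntheticSpec) -> tuple[PerturbationMatrix, pd.DataFrame]:
    """Simulate raw data, z-normalize, and package matrix + truth table."""
    raw = simulate_raw(spec)
    z = z_normalize(raw.expression, raw.control_ids, raw.gemgroup)
    truth = raw.truth
    pert_meta = pd.DataFrame(
        {
            "target_gene": truth["target_gene"],
            "knockdown_fraction": truth["knockdown_fraction"],
            "class_label": truth["class"],
            "gemgroup": raw.gemgroup.reindex(truth.index),
        }
    )
    m = PerturbationMatrix(
        genes=list(z.columns),
        perturbations=list(z.index),
        z=z.to_numpy(),
        pert_meta=pert_meta.loc[z.index],
    )
    return m, truth.reset_index()


def expected_null_z_sd(n_controls: int) -> float:
    """Exact SD of a null z-score normalized against estimated control stats.

    Normalizing a normal draw by the mean and sample SD of n independent
    control draws gives a scaled t-variate: its SD is
    sqrt((1 + 1/n) · (n − 1)/(n − 3)), slightly above 1 for finite n
    (≈ 1.006 at the default 250 controls per gemgroup).  Useful as the
    oracle when checking that null perturbation z-scores are (nearly)
    standard.
    """
    if n_controls < 4:
        raise ValueError("SD undefined for fewer than 4 control sgRNAs")
    return float(
        np.sqrt((1 + 1 / n_controls) * (n_controls - 1) / (n_controls - 3))
    )


def simulate_null_matrix(
    n_perturbations: int,
    genes: list[str] | None = None,
    n_genes: int = 2000,
    seed: int = 0,
) -> PerturbationMatrix:
    """Matrix of exactly iid standard-normal z — the analysis's null model.

    A fast path for calibration studies; bypasses the raw/normalization
    pipeline (which only approximates standard-normal nulls because the
    control mean and SD are estimated).
    """
    if genes is None:
        genes = SyntheticSpec(n_genes=n_genes, classes={}, n_per_class={}).gene_panel
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_perturbations, len(genes)))
    perts = [f"NULL_{i:04d}" for i in range(n_perturbations)]
    return PerturbationMatrix(genes=list(genes), perturbations=perts, z=z)
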