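"""Pseudobulk perturbation × gene z-score matrices and their on-disk dialects.

A pseudobulk matrix holds one z-normalized expression vector per CRISPRi
perturbation: each entry is the gene's pseudobulk expression in standard
deviations relative to the mean and SD of control-sgRNA cells from the
same 10X gemgroup.  Two dialects are supported:

* ``h5ad`` — the AnnData on-disk layout used by the published resource:
  X carries the z-scores, ``obs`` the per-perturbation metadata
  (including ``fraction knockdown``), ``var`` the per-gene flags.
* ``tsv`` — a plain-text dialect (genes as columns) with two sidecar
  metadata tables, so fixtures need no HDF5 tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .genesets import FactorList, _normalize_symbol

logger = logging.getLogger(__name__)

#: obs column name used by the published h5ad resource for knockdown efficiency
H5AD_KNOCKDOWN_KEY = "fraction knockdown"

PERT_META_COLUMNS = ("target_gene", "knockdown_fraction", "class_label")


class PseudobulkLoadError(ValueError):
    """Raised when a pseudobulk file is malformed or inconsistent."""


@dataclass
class PerturbationMatrix:
    """Dense perturbations × genes z-score matrix with metadata.

    Attributes
    ----------
    genes : list of str
        Ordered, unique, uppercase gene symbols (columns of ``z``).
    perturbations : list of str
        Ordered, unique perturbation identifiers (rows of ``z``).
    z : ndarray of shape (n_perturbations, n_genes)
        z-normalized expression; NaN-free after load.
    pert_meta : DataFrame indexed by perturbation
        Columns ``target_gene``, ``knockdown_fraction`` (in [0, 1] or
        NaN), ``class_label``.
    gene_meta : DataFrame indexed by gene
        Boolean flag columns; ``mtdna_encoded`` is filled from the
        standard "MT-" symbol prefix if absent.
    """

    genes: list[str]
    perturbations: list[str]
    z: np.ndarray
    pert_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    gene_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genes = [_normalize_symbol(g) for g in self.genes]
        self.perturbations = [str(p) for p in self.perturbations]
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.perturbations), len(self.genes)):
            raise PseudobulkLoadError(
                f"z shape {self.z.shape} does not match "
                f"{len(self.perturbations)} perturbations × {len(self.genes)} genes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise PseudobulkLoadError("gene symbols are not unique")
        if len(set(self.perturbations)) != len(self.perturbations):
            raise PseudobulkLoadError("perturbation identifiers are not unique")
        if np.isnan(self.z).any():
            raise PseudobulkLoadError(
                "z matrix contains NaN; load with missing='zero' or "
                "missing='drop' to resolve"
            )

        if self.pert_meta is None:
            self.pert_meta = pd.DataFrame(index=self.perturbations)
        else:
            self.pert_meta = self.pert_meta.copy()
            if len(self.pert_meta) != len(self.perturbations):
                raise PseudobulkLoadError(
                    f"pert_meta has {len(self.pert_meta)} rows for "
                    f"{len(self.perturbations)} perturbations"
                )
            self.pert_meta.index = pd.Index(self.perturbations)
        if "target_gene" not in self.pert_meta:
            # default: the perturbation id names its target
            self.pert_meta["target_gene"] = [
                _normalize_symbol(p.split("_")[0]) for p in self.perturbations
            ]
        else:
            self.pert_meta["target_gene"] = [
                _normalize_symbol(str(t)) for t in self.pert_meta["target_gene"]
            ]
        if "knockdown_fraction" not in self.pert_meta:
            self.pert_meta["knockdown_fraction"] = np.nan
        kd = pd.to_numeric(self.pert_meta["knockdown_fraction"], errors="coerce")
        bad = kd.dropna()[(kd.dropna() < 0) | (kd.dropna() > 1)]
        if len(bad):
            raise PseudobulkLoadError(
                f"knockdown_fraction outside [0, 1] for {list(bad.index[:5])}"
            )
        self.pert_meta["knockdown_fraction"] = kd
        if "class_label" not in self.pert_meta:
            self.pert_meta["class_label"] = pd.NA

        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=self.genes)
        else:
            self.gene_meta = self.gene_meta.copy()
            if len(self.gene_meta) != len(self.genes):
                raise PseudobulkLoadError(
                    f"gene_meta has {len(self.gene_meta)} rows for "
                    f"{len(self.genes)} genes"
                )
            self.gene_meta.index = pd.Index(self.genes)
        if "mtdna_encoded" not in self.gene_meta:
            self.gene_meta["mtdna_encoded"] = [
                g.startswith("MT-") for g in self.genes
            ]
        else:
            self.gene_meta["mtdna_encoded"] = (
                self.gene_meta["mtdna_encoded"].astype(bool)
            )

    # -- basic accessors ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Column indices of *genes* (order preserved); unknown gene raises."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        try:
            return np.array([lookup[_normalize_symbol(g)] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in matrix panel") from None

    def pert_index(self, pert: str) -> int:
        try:
            return self.perturbations.index(str(pert))
        except ValueError:
            raise KeyError(f"perturbation {pert!r} not in matrix") from None

    def profile(self, pert: str) -> pd.Series:
        """The z-score vector of one perturbation, indexed by gene."""
        return pd.Series(self.z[self.pert_index(pert)], index=self.genes, name=pert)

    def set_values(self, pert: str, genes: Sequence[str]) -> np.ndarray:
        """z-values of *genes* for one perturbation, in gene-list order."""
        return self.z[self.pert_index(pert), self.gene_index(genes)]

    def to_anndata(self) -> ad.AnnData:
        obs = self.pert_meta.copy()
        obs[H5AD_KNOCKDOWN_KEY] = obs.pop("knockdown_fraction")
        obs.index = obs.index.astype(str)
        var = self.gene_meta.copy()
        var.index = var.index.astype(str)
        return ad.AnnData(X=self.z.copy(), obs=obs, var=var)


def from_anndata(adata: ad.AnnData) -> PerturbationMatrix:
    """Build a :class:`PerturbationMatrix` from an AnnData object.

    ``obs['fraction knockdown']`` (the published resource's key) or
    ``obs['knockdown_fraction']`` populates the knockdown metadata.
    """
    X = adata.X
    if hasattr(X, "toarray"):  # sparse
        X = X.toarray()
    pert_meta = adata.obs.copy()
    if H5AD_KNOCKDOWN_KEY in pert_meta:
        pert_meta = pert_meta.rename(
            columns={H5AD_KNOCKDOWN_KEY: "knockdown_fraction"}
        )
    return PerturbationMatrix(
        genes=list(adata.var_names),
        perturbations=list(adata.obs_names),
        z=np.asarray(X, dtype=float),
        pert_meta=pert_meta,
        gene_meta=adata.var.copy(),
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _tsv_sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return (
        stem.with_name(stem.name + ".pert_meta.tsv"),
        stem.with_name(stem.name + ".gene_meta.tsv"),
    )


def _apply_missing_policy(z: np.ndarray, perts: list[str], missing: str):
    n_missing = int(np.isnan(z).sum())
    if n_missing == 0:
        return z, perts
    if missing == "error":
        raise PseudobulkLoadError(
            f"{n_missing} missing z values; pass missing='zero' or 'drop'"
        )
    if missing == "zero":
        logger.warning("zero-filled %d missing z values", n_missing)
        return np.nan_to_num(z, nan=0.0), perts
    if missing == "drop":
        keep = ~np.isnan(z).any(axis=1)
        logger.warning(
            "dropped %d perturbation rows with missing z", int((~keep).sum())
        )
        return z[keep], [p for p, k in zip(perts, keep) if k]
    raise ValueError(f"unknown missing policy {missing!r}")


def read_pseudobulk(
    path: str | Path, dialect: str = "h5ad", missing: str = "error"
) -> PerturbationMatrix:
    """Read a pseudobulk z-score matrix.

    Parameters
    ----------
    path : path
        For ``dialect='tsv'`` this is the matrix TSV; the metadata
        sidecars ``<stem>.pert_meta.tsv`` / ``<stem>.gene_meta.tsv`` are
        read if present.
    dialect : {'h5ad', 'tsv'}
    missing : {'error', 'zero', 'drop'}
        Policy for missing z values; the default refuses them, 'zero'
        imputes 0 and 'drop' removes the affected rows (both logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "h5ad":
        m = from_anndata(ad.read_h5ad(path))
        if np.isnan(m.z).any():  # pragma: no cover - rebuilt below
            z, perts = _apply_missing_policy(m.z, m.perturbations, missing)
            m = PerturbationMatrix(m.genes, perts, z, m.pert_meta.loc[perts], m.gene_meta)
    elif dialect == "tsv":
        m = _read_tsv(path, missing=missing)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'h5ad' or 'tsv'")
    n_kd = int(m.pert_meta["knockdown_fraction"].isna().sum())
    logger.info(
        "loaded %s: %d perturbations × %d genes; %d/%d missing knockdown fractions",
        path, m.shape[0], m.shape[1], n_kd, m.shape[0],
    )
    return m


def _read_tsv(path: Path, missing: str = "error") -> PerturbationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    pm_path, gm_path = _tsv_sidecar_paths(path)
    pert_meta = (
        pd.read_csv(pm_path, sep="\t", index_col=0, float_precision="round_trip")
        if pm_path.exists()
        else None
    )
    gene_meta = (
        pd.read_csv(gm_path, sep="\t", index_col=0) if gm_path.exists() else None
    )

    # Orientation sniff: rows should be perturbations.  If the metadata
    # sidecar length matches the column count instead, the matrix was
    # written transposed; flip it and record the decision.
    if pert_meta is not None and len(pert_meta) != len(df.index):
        if len(pert_meta) == len(df.columns):
            logger.warning(
                "TSV matrix %s appears transposed (perturbations as "
                "columns); transposing on load", path,
            )
            df = df.T
        else:
            raise PseudobulkLoadError(
                f"pert_meta has {len(pert_meta)} rows but matrix has "
                f"{len(df.index)} rows / {len(df.columns)} columns"
            )

    z = df.to_numpy(dtype=float)
    perts = [str(i) for i in df.index]
    z, perts = _apply_missing_policy(z, perts, missing)
    if pert_meta is not None and len(perts) != len(pert_meta):
        pert_meta = pert_meta.loc[[str(p) for p in perts]]
    return PerturbationMatrix(
        genes=list(df.columns),
        perturbations=perts,
        z=z,
        pert_meta=pert_meta,
        gene_meta=gene_meta,
    )


def write_pseudobulk(
    m: PerturbationMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write *m* in the given dialect (TSV emits two metadata sidecars)."""
    path = Path(path)
    if dialect == "h5ad":
        m.to_anndata().write_h5ad(path)
        return
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.DataFrame(m.z, index=m.perturbations, columns=m.genes)
    df.index.name = "perturbation"
    # repr-roundtrip precision so write→read is bit-identical
    df.to_csv(path, sep="\t", float_format="%.17g")
    pm_path, gm_path = _tsv_sidecar_paths(path)
    pm = m.pert_meta.copy()
    pm.index.name = "perturbation"
    pm.to_csv(pm_path, sep="\t", float_format="%.17g")
    gm = m.gene_meta.copy()
    gm.index.name = "gene"
    gm.to_csv(gm_path, sep="\t")


# ---------------------------------------------------------------------------
# Subsetting and annotation
# ---------------------------------------------------------------------------


def select_perturbations(
    m: PerturbationMatrix, targets: FactorList | Iterable[str]
) -> tuple[PerturbationMatrix, list[str]]:
    """Keep perturbations whose target gene is in *targets*.

    Returns the row-sliced matrix (gene order untouched) and the list of
    requested targets absent from the matrix.  An empty intersection is
    a hard error.
    """
    wanted = list(targets.members if isinstance(targets, FactorList) else targets)
    if not wanted:
        raise ValueError("empty target list")
    wanted_norm = [_normalize_symbol(t) for t in wanted]
    wanted_set = set(wanted_norm)

    mask = m.pert_meta["target_gene"].isin(wanted_set).to_numpy()
    if not mask.any():
        raise ValueError(
            f"none of the {len(wanted_set)} requested targets are present "
            "in the matrix"
        )
    present = set(m.pert_meta.loc[mask, "target_gene"])
    missing = [t for t in dict.fromkeys(wanted_norm) if t not in present]
    if missing:
        logger.info("%d requested targets absent from matrix", len(missing))
    kept = [p for p, k in zip(m.perturbations, mask) if k]
    sub = PerturbationMatrix(
        genes=list(m.genes),
        perturbations=kept,
        z=m.z[mask],
        pert_meta=m.pert_meta.loc[kept],
        gene_meta=m.gene_meta,
    )
    return sub, missing


def annotate_gene_classes(
    m: PerturbationMatrix,
    class_name: str,
    members: Iterable[str],
    overwrite: bool = False,
) -> PerturbationMatrix:
    """Flag a gene class (e.g. mtDNA-encoded) in ``gene_meta``.

    Zero matching panel genes is a logged warning, not an error.  The
    matrix is modified in place and returned for chaining.
    """
    if class_name in m.gene_meta.columns and not overwrite:
        raise ValueError(
            f"gene class {class_name!r} already annotated; pass overwrite=True"
        )
    member_set = {_normalize_symbol(g) for g in members}
    flags = [g in member_set for g in m.genes]
    n = sum(flags)
    if n == 0:
        logger.warning("gene class %r: no members in panel", class_name)
    else:
        logger.info("gene class %r: flagged %d genes", class_name, n)
    m.gene_meta[class_name] = flags
    return m
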