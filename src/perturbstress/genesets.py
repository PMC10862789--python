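"""Stress-pathway gene-set panels and proteostasis factor lists.

Gene sets are small panels (10–20 genes) of transcriptional targets
regulated downstream of stress-responsive signaling pathways — the
integrated stress response (ISR), the ER unfolded protein response
(UPR, including its ATF6 and IRE1/XBP1s arms), the heat shock response
(HSR) and the oxidative stress response (OSR) — plus a designated
control set of stably expressed genes that serves as the null reference
group for significance testing.

Sets are read and written in the Broad GMT dialect (one set per line:
name, description, then member genes, tab-separated).  Gene symbols are
normalized to uppercase and matched by exact string equality; member
order follows the source file so that heatmap row order is reproducible.

The packaged panels under ``resources/`` are synthetic stand-ins with
field-typical member genes; they are not transcriptions of any published
supplement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Recognized pathway labels; GMT set names matching one of these
#: (case-insensitively) are labelled accordingly, anything else is "custom".
KNOWN_PATHWAY_LABELS = ("UPR", "ISR", "HSR", "OSR", "ATF6", "IRE1_XBP1S", "CONTROL")

_RESOURCE_PACKAGE = "perturbstress.resources"
STRESS_PANEL_RESOURCE = "stress_panels_synthetic.gmt"
FACTOR_LIST_RESOURCE = "factor_lists_synthetic.tsv"


class GeneSetFormatError(ValueError):
    """Raised for malformed GMT or factor-list input."""


def _normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named panel of gene symbols attributed to one stress pathway.

    Parameters
    ----------
    name : str
        Short identifier, unique within a collection.
    pathway_label : str
        One of :data:`KNOWN_PATHWAY_LABELS` or ``"custom"``.
    genes : tuple of str
        Ordered, uppercase, duplicate-free member symbols.  Order is
        preserved from the source file and drives heatmap row order.
    source : str
        Free-text provenance.
    """

    name: str
    pathway_label: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        normalized = tuple(_normalize_symbol(g) for g in self.genes)
        if not normalized:
            raise GeneSetFormatError(f"gene set {self.name!r} has no genes")
        if len(set(normalized)) != len(normalized):
            dupes = sorted({g for g in normalized if normalized.count(g) > 1})
            raise GeneSetFormatError(
                f"gene set {self.name!r} has duplicate symbols after "
                f"case normalization: {dupes}"
            )
        object.__setattr__(self, "genes", normalized)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return _normalize_symbol(symbol) in self.genes

    def restrict_to(self, panel: Iterable[str]) -> "GeneSet":
        """Return a copy keeping only genes present in *panel* (order kept)."""
        panel_set = {_normalize_symbol(g) for g in panel}
        kept = tuple(g for g in self.genes if g in panel_set)
        if not kept:
            raise ValueError(
                f"gene set {self.name!r} has no members in the measured panel"
            )
        return GeneSet(self.name, self.pathway_label, kept, self.source)


def _infer_pathway_label(name: str) -> str:
    upper = name.strip().upper()
    return upper if upper in KNOWN_PATHWAY_LABELS else "custom"


@dataclass
class GeneSetCollection:
    """A mapping of named gene sets with one designated control set."""

    sets: dict[str, GeneSet]
    control_name: str

    def __post_init__(self) -> None:
        if self.control_name not in self.sets:
            raise GeneSetFormatError(
                f"control set {self.control_name!r} not present in collection"
            )
        control_labelled = [
            s.name for s in self.sets.values() if s.pathway_label == "CONTROL"
        ]
        if len(control_labelled) > 1:
            raise GeneSetFormatError(
                f"more than one set labelled CONTROL: {control_labelled}"
            )

    @property
    def control(self) -> GeneSet:
        return self.sets[self.control_name]

    @property
    def pathway_sets(self) -> dict[str, GeneSet]:
        """All member sets except the control set."""
        return {k: v for k, v in self.sets.items() if k != self.control_name}

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def all_genes(self) -> tuple[str, ...]:
        """Union of member genes, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sets.values():
            for g in s.genes:
                seen.setdefault(g)
        return tuple(seen)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        """Collection restricted to *names* plus the control set."""
        keep = list(dict.fromkeys(list(names) + [self.control_name]))
        return GeneSetCollection(
            {n: self.sets[n] for n in keep}, control_name=self.control_name
        )


@dataclass(frozen=True)
class FactorList:
    """A curated list of perturbation-target genes (e.g. a proteostasis network).

    ``sublist`` groups members into pathways (chaperones, proteases,
    import, targeting, ...) and is used to order heatmap columns.
    """

    list_name: str
    members: tuple[str, ...]
    sublist: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = tuple(_normalize_symbol(g) for g in self.members)
        if len(set(normalized)) != len(normalized):
            raise GeneSetFormatError(
                f"factor list {self.list_name!r} has duplicate members"
            )
        object.__setattr__(self, "members", normalized)
        object.__setattr__(
            self,
            "sublist",
            {_normalize_symbol(k): v for k, v in dict(self.sublist).items()},
        )

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# GMT parsing / writing
# ---------------------------------------------------------------------------


def parse_gmt(
    source: str | Path | IO[str], control_name: str = "CONTROL"
) -> GeneSetCollection:
    """Parse a GMT stream or path into a :class:`GeneSetCollection`.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Symbols
    are uppercased; gene order within each set is preserved.  The control
    set is the set whose name equals *control_name* after normalization.

    Raises
    ------
    GeneSetFormatError
        On an empty file, duplicate set names, or a line with no genes.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()

    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GeneSetFormatError(
                f"line {lineno}: expected name, description and at least "
                f"one gene, got {len(fields)} fields"
            )
        name, description, genes = fields[0].strip(), fields[1], fields[2:]
        genes = [g for g in genes if g.strip()]
        if not genes:
            raise GeneSetFormatError(f"line {lineno}: set {name!r} lists no genes")
        if name in sets:
            raise GeneSetFormatError(f"duplicate set name {name!r} (line {lineno})")
        sets[name] = GeneSet(
            name=name,
            pathway_label=_infer_pathway_label(name),
            genes=tuple(genes),
            source=description,
        )
    if not sets:
        raise GeneSetFormatError("empty GMT input: no gene sets found")
    if control_name not in sets:
        raise GeneSetFormatError(
            f"control set {control_name!r} not found; sets: {sorted(sets)}"
        )
    return GeneSetCollection(sets=sets, control_name=control_name)


def write_gmt(collection: GeneSetCollection, target: str | Path | IO[str]) -> None:
    """Write *collection* in GMT dialect; inverse of :func:`parse_gmt`."""
    lines = [
        "\t".join([s.name, s.source, *s.genes]) for s in collection.sets.values()
    ]
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text)


# ---------------------------------------------------------------------------
# Validation and panel mapping
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Report-only audit of a collection's invariants."""

    set_sizes: dict[str, int]
    control_overlaps: dict[str, tuple[str, ...]]
    violations: list[str]

    @property
    def passed(self) -> bool:
        return not self.violations


def validate_collection(collection: GeneSetCollection) -> ValidationReport:
    """Audit set sizes and control/pathway overlaps without raising.

    A collection passes iff the control set shares no gene with any
    pathway set.  (Duplicate symbols within a set and duplicate set
    names are rejected at construction time and cannot reach here.)
    """
    sizes = {name: len(s) for name, s in collection.sets.items()}
    control_genes = set(collection.control.genes)
    overlaps: dict[str, tuple[str, ...]] = {}
    violations: list[str] = []
    for name, s in collection.pathway_sets.items():
        shared = tuple(g for g in s.genes if g in control_genes)
        if shared:
            overlaps[name] = shared
            violations.append(
                f"control set overlaps pathway set {name!r} "
                f"({len(shared)} gene(s): {', '.join(shared)})"
            )
    return ValidationReport(
        set_sizes=sizes, control_overlaps=overlaps, violations=violations
    )


def map_to_panel(
    collection: GeneSetCollection,
    panel: Iterable[str],
    min_fraction: float = 0.5,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Restrict every set to the genes measured in *panel*.

    Returns the mapped collection and a coverage table with columns
    ``set``, ``n_total``, ``n_mapped``, ``coverage``, ``flagged``.
    Sets whose coverage falls below *min_fraction* are flagged (and a
    warning logged for any coverage below 1.0); a set with zero mapped
    genes is a hard error naming the set.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    panel_list = [_normalize_symbol(g) for g in panel]
    if not panel_list:
        raise ValueError("measured gene panel is empty")
    panel_set = set(panel_list)

    mapped: dict[str, GeneSet] = {}
    rows = []
    for name, s in collection.sets.items():
        kept = tuple(g for g in s.genes if g in panel_set)
        if not kept:
            raise ValueError(
                f"gene set {name!r} has no members in the measured panel"
            )
        coverage = len(kept) / len(s)
        flagged = coverage < min_fraction
        if coverage < 1.0:
            logger.warning(
                "gene set %r: %d/%d members measured (coverage %.2f)%s",
                name, len(kept), len(s), coverage,
                " — below min_fraction" if flagged else "",
            )
        mapped[name] = GeneSet(s.name, s.pathway_label, kept, s.source)
        rows.append(
            {
                "set": name,
                "n_total": len(s),
                "n_mapped": len(kept),
                "coverage": coverage,
                "flagged": flagged,
            }
        )
    coverage_table = pd.DataFrame(rows).set_index("set")
    return (
        GeneSetCollection(sets=mapped, control_name=collection.control_name),
        coverage_table,
    )


# ---------------------------------------------------------------------------
# Packaged resources
# ---------------------------------------------------------------------------


def load_stress_panels() -> GeneSetCollection:
    """Load the packaged stress-pathway panels (synthetic stand-ins).

    The collection contains ISR (13 genes), UPR (20), HSR (12), OSR (12),
    the ATF6 and IRE1/XBP1s UPR arms (10 each) and a 19-gene control set.
    Member symbols are field-typical but synthetic stand-ins, not a
    transcription of any published supplement.
    """
    ref = _importlib_resources.files(_RESOURCE_PACKAGE) / STRESS_PANEL_RESOURCE
    with ref.open("r") as fh:
        return parse_gmt(fh)


def parse_factor_lists(source: str | Path | IO[str]) -> dict[str, FactorList]:
    """Parse a TSV of (list_name, sublist, gene) rows into FactorLists."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"list_name", "sublist", "gene"}
    if not required.issubset(df.columns):
        raise GeneSetFormatError(
            f"factor list TSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    lists: dict[str, FactorList] = {}
    for list_name, grp in df.groupby("list_name", sort=False):
        members = tuple(grp["gene"])
        sublist = dict(zip(grp["gene"], grp["sublist"]))
        lists[list_name] = FactorList(list_name, members, sublist)
    return lists


def load_factor_lists() -> dict[str, FactorList]:
    """Load the packaged proteostasis factor lists (synthetic stand-ins).

    Provides ``er_proteostasis``, ``mito_proteostasis`` and ``mitocarta``
    lists with field-typical members; these are synthetic stand-ins, much
    smaller than real curated proteostasis annotations.
    """
    ref = _importlib_resources.files(_RESOURCE_PACKAGE) / FACTOR_LIST_RESOURCE
    with ref.open("r") as fh:
        return parse_factor_lists(fh)
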