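"""Domain types, TSV readers/writers and stress-condition classification.

All tabular interchange formats are tab-separated with a header row; the
missing-value token is the empty string. Gene identifiers are opaque,
case-sensitive strings.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "StressCondition",
    "ExpressionMatrix",
    "DEGTable",
    "OrthogroupMap",
    "BinHierarchy",
    "TFTable",
    "classify_condition",
    "parse_level",
    "read_orthogroups",
    "write_orthogroups",
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "read_bins",
    "write_bins",
    "read_tf_table",
    "read_deg_table",
    "write_deg_table",
    "read_besthits",
    "sample_similarity",
]


class Category(str, Enum):
    """Position of a stress level relative to its experiment's control."""

    DEFICIENT = "deficient"
    SURPLUS = "surplus"
    CONTROL = "control"
    OTHER = "other"


@dataclass(frozen=True)
class StressCondition:
    """One stress treatment of one species: an experiment axis plus a level.

    ``category`` records whether the level sits above (surplus) or below
    (deficient) the control level of its experiment; non-ordinal axes such
    as light-quality ratios are ``other``.
    """

    species: str
    experiment: str
    level: str
    category: Category

    @property
    def label(self) -> str:
        return f"{self.experiment}:{self.level}"


_NUM_RE = re.compile(r"^\s*([+-]?\d+(?:\.\d+)?)\s*(?:%|C|h|K)?\s*$")


def parse_level(level: str) -> float | None:
    """Parse an ordinal stress level ("150%", "35C", "8h") to a number.

    Returns ``None`` for non-ordinal labels (e.g. light-quality ratios
    like "4:1:0").
    """
    m = _NUM_RE.match(str(level))
    return float(m.group(1)) if m else None


def classify_condition(
    experiment: str, level: str, control_level: str | None
) -> Category:
    """Classify a stress level as surplus/deficient/control relative to control.

    Levels are compared numerically on the experiment's ordinal axis; a level
    above the control level is a surplus, below is a deficiency. Axes whose
    levels do not parse as numbers (light-quality ratios) are ``other``.
    """
    value = parse_level(level)
    if value is None:
        return Category.OTHER
    if control_level is None:
        raise ValueError(
            f"experiment {experiment!r} has ordinal levels but no control level"
        )
    control = parse_level(control_level)
    if control is None:
        raise ValueError(
            f"control level {control_level!r} of experiment {experiment!r} "
            "is not ordinal"
        )
    if value > control:
        return Category.SURPLUS
    if value < control:
        return Category.DEFICIENT
    return Category.CONTROL


# ---------------------------------------------------------------------------
# Expression matrix + design


DESIGN_COLUMNS = ["sample_id", "species", "experiment", "level", "replicate"]


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance for one species, with its sample design.

    ``values`` is a genes x samples DataFrame (index = gene ids, columns =
    sample ids); ``design`` holds one row per sample with columns
    ``sample_id, species, experiment, level, replicate`` plus a derived
    ``category`` column. ``unit`` records whether the values are raw counts,
    CPM or TPM.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing = set(self.values.columns) - set(self.design["sample_id"])
        if missing:
            raise ValueError(f"samples without a design row: {sorted(missing)}")
        if "category" not in self.design.columns:
            self.design = annotate_categories(self.design)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def species(self) -> str:
        return str(self.design["species"].iloc[0])

    def condition_labels(self) -> list[str]:
        labels = (
            self.design["experiment"].astype(str)
            + ":"
            + self.design["level"].astype(str)
        )
        return list(dict.fromkeys(labels))

    def samples_of(self, experiment: str, level: str) -> list[str]:
        d = self.design
        sel = d[(d["experiment"] == experiment) & (d["level"].astype(str) == str(level))]
        return [s for s in sel["sample_id"] if s in self.values.columns]

    def control_level(self, experiment: str) -> str | None:
        d = self.design
        sel = d[(d["experiment"] == experiment) & (d["category"] == Category.CONTROL.value)]
        if sel.empty:
            return None
        return str(sel["level"].iloc[0])


def annotate_categories(design: pd.DataFrame) -> pd.DataFrame:
    """Derive the surplus/deficient/control/other category for every design row.

    The control level of each (species, experiment) is the row whose
    ``level`` equals the design's designated control; the design marks it
    with ``category == control`` if present, otherwise the level named
    "100%" or, failing that, the experiment errors for ordinal axes. The
    convention used throughout: a design table may carry an explicit
    ``control`` column (0/1); otherwise "100%" is assumed for percentage
    axes and the category column must be supplied for other axes via the
    ``control_level`` mapping in :func:`read_design`.
    """
    design = design.copy()
    cats: list[str] = []
    control_of: dict[tuple[str, str], str | None] = {}
    for (sp, exp), grp in design.groupby(["species", "experiment"], sort=False):
        ctrl = None
        if "control" in grp.columns:
            flagged = grp[grp["control"].astype(int) == 1]
            if not flagged.empty:
                ctrl = str(flagged["level"].iloc[0])
        if ctrl is None:
            levels = [str(x) for x in grp["level"].unique()]
            if "100%" in levels:
                ctrl = "100%"
        control_of[(str(sp), str(exp))] = ctrl
    for _, row in design.iterrows():
        exp, level = str(row["experiment"]), str(row["level"])
        ctrl = control_of[(str(row["species"]), exp)]
        if parse_level(level) is None:
            # non-ordinal axis: the flagged control keeps its label
            if ctrl is not None and level == ctrl:
                cats.append(Category.CONTROL.value)
            else:
                cats.append(Category.OTHER.value)
        else:
            cats.append(classify_condition(exp, level, ctrl).value)
    design["category"] = cats
    return design


def read_expression(path: str | Path, design: pd.DataFrame, unit: str = "counts") -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionMatrix(values=values, design=design, unit=unit)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"level": str})
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return annotate_categories(design)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in DESIGN_COLUMNS + ["control", "category"] if c in design.columns]
    design[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DEG table


@dataclass
class DEGTable:
    """Genes passing the DEG rule for one stress-vs-control contrast.

    Every row satisfies ``|log2FC| >= fc_threshold`` and
    ``p_adj <= p_threshold``; ``direction`` is the sign of log2FC.
    """

    table: pd.DataFrame  # columns: gene, log2FC, p_adj, direction
    species: str
    experiment: str
    level: str
    fc_threshold: float = 1.0
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        t = self.table
        if len(t):
            if (t["log2FC"].abs() < self.fc_threshold - 1e-12).any():
                raise ValueError("DEGTable row below the fold-change threshold")
            if (t["p_adj"] > self.p_threshold + 1e-12).any():
                raise ValueError("DEGTable row above the adjusted-p threshold")
            expect = np.where(t["log2FC"] > 0, "up", "down")
            if (t["direction"].to_numpy() != expect).any():
                raise ValueError("direction inconsistent with sign(log2FC)")

    @property
    def condition_label(self) -> str:
        return f"{self.experiment}:{self.level}"

    def genes(self, direction: str | None = None) -> set[str]:
        t = self.table
        if direction is not None:
            t = t[t["direction"] == direction]
        return set(t["gene"])


def read_deg_table(path: str | Path, species: str, experiment: str, level: str,
                   fc_threshold: float = 1.0, p_threshold: float = 0.05) -> DEGTable:
    """Load an externally computed DEG table (gene, log2FC, p_adj).

    Rows failing the thresholds are dropped so the invariants hold even for
    unfiltered input; a ``direction`` column is derived if absent.
    """
    t = pd.read_csv(path, sep="\t")
    t = t[(t["log2FC"].abs() >= fc_threshold) & (t["p_adj"] <= p_threshold)].copy()
    if "direction" not in t.columns:
        t["direction"] = np.where(t["log2FC"] > 0, "up", "down")
    t = t[["gene", "log2FC", "p_adj", "direction"]]
    return DEGTable(table=t.reset_index(drop=True), species=species,
                    experiment=experiment, level=level,
                    fc_threshold=fc_threshold, p_threshold=p_threshold)


def write_deg_table(deg: DEGTable, path: str | Path) -> None:
    out = deg.table.copy()
    out.insert(0, "species", deg.species)
    out.insert(1, "experiment", deg.experiment)
    out.insert(2, "level", deg.level)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Orthogroups


@dataclass
class OrthogroupMap:
    """Many-to-many gene <-> orthogroup assignment across species.

    A gene belongs to at most one orthogroup; an orthogroup may hold any
    number of genes per species (including zero).
    """

    assignments: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._members: dict[str, set[tuple[str, str]]] = {}
        for (sp, gene), og in self.assignments.items():
            self._members.setdefault(og, set()).add((sp, gene))

    def og_of(self, species: str, gene: str) -> str | None:
        return self.assignments.get((species, gene))

    def members(self, og: str) -> set[tuple[str, str]]:
        return self._members.get(og, set())

    def members_of_species(self, og: str, species: str) -> set[str]:
        return {g for sp, g in self.members(og) if sp == species}

    @property
    def orthogroup_ids(self) -> list[str]:
        return sorted(self._members)

    def species_of(self, og: str) -> set[str]:
        return {sp for sp, _ in self.members(og)}

    def ogs_with_species(self, species: Iterable[str]) -> set[str]:
        want = set(species)
        return {og for og in self._members if want <= self.species_of(og)}

    def genes_of_species(self, species: str) -> set[str]:
        return {g for (sp, g) in self.assignments if sp == species}


def read_orthogroups(path: str | Path) -> OrthogroupMap:
    """Parse an OrthoFinder-style Orthogroups.tsv.

    First column is the orthogroup id; each further column is one species
    holding a comma-separated gene list (empty cell = no members). A gene
    listed under two orthogroups is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    species_cols = list(df.columns[1:])
    if not species_cols:
        raise ValueError("Orthogroups table has no species columns")
    assignments: dict[tuple[str, str], str] = {}
    for _, row in df.iterrows():
        og = row.iloc[0]
        for sp in species_cols:
            cell = row[sp]
            if not cell.strip():
                continue
            for gene in (g.strip() for g in cell.split(",")):
                if not gene:
                    continue
                key = (sp, gene)
                if key in assignments and assignments[key] != og:
                    raise ValueError(
                        f"gene {gene!r} of species {sp!r} listed under both "
                        f"{assignments[key]!r} and {og!r}"
                    )
                assignments[key] = og
    return OrthogroupMap(assignments=assignments)


def write_orthogroups(ogmap: OrthogroupMap, path: str | Path) -> None:
    species = sorted({sp for sp, _ in ogmap.assignments})
    rows = []
    for og in ogmap.orthogroup_ids:
        row = {"Orthogroup": og}
        for sp in species:
            row[sp] = ", ".join(sorted(ogmap.members_of_species(og, sp)))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *species]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Functional bin hierarchy


@dataclass
class BinHierarchy:
    """Hierarchical functional bins (dot-separated codes, level = depth).

    ``genes[(species, code)]`` is the gene set of a bin for a species; a
    gene assigned to a bin is a member of every ancestor bin as well, so
    child sets are subsets of parent sets within a species.
    """

    names: dict[str, str] = field(default_factory=dict)  # code -> name
    genes: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @staticmethod
    def level(code: str) -> int:
        return code.count(".") + 1

    @staticmethod
    def ancestors(code: str) -> list[str]:
        parts = code.split(".")
        return [".".join(parts[: i + 1]) for i in range(len(parts))]

    def add_gene(self, species: str, gene: str, code: str, name: str = "") -> None:
        for anc in self.ancestors(code):
            self.genes.setdefault((species, anc), set()).add(gene)
            self.names.setdefault(anc, name if anc == code else "")
        if name:
            self.names[code] = name

    def bin_codes(self, level: int | None = None) -> list[str]:
        codes = {c for (_, c) in self.genes}
        if level is not None:
            codes = {c for c in codes if self.level(c) == level}
        return sorted(codes, key=lambda c: [int(x) if x.isdigit() else x for x in c.split(".")])

    def size(self, species: str, code: str) -> int:
        return len(self.genes.get((species, code), ()))

    def gene_set(self, species: str, code: str) -> set[str]:
        return self.genes.get((species, code), set())

    def bins_of_gene(self, species: str, gene: str) -> set[str]:
        return {c for (sp, c), gs in self.genes.items() if sp == species and gene in gs}


def read_bins(path: str | Path) -> BinHierarchy:
    """Read a bin annotation table (species, gene_id, bin_code, bin_name).

    Each row assigns one gene to one terminal bin; membership propagates to
    all ancestor bins. A gene may appear in several rows (multiple bins).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    hierarchy = BinHierarchy()
    for row in df.itertuples(index=False):
        hierarchy.add_gene(row.species, row.gene_id, row.bin_code, row.bin_name)
    return hierarchy


def write_bins(rows: pd.DataFrame, path: str | Path) -> None:
    rows[["species", "gene_id", "bin_code", "bin_name"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# TF table


@dataclass
class TFTable:
    """Transcription factors and their families, one row per (species, gene)."""

    table: pd.DataFrame  # columns: species, gene_id, family

    def __post_init__(self) -> None:
        t = self.table
        if (t["family"].astype(str).str.len() == 0).any():
            raise ValueError("empty TF family label")
        if t.duplicated(["species", "gene_id"]).any():
            raise ValueError("duplicate (species, gene) row in TF table")

    def tfs_of(self, species: str) -> list[str]:
        t = self.table
        return list(t.loc[t["species"] == species, "gene_id"])

    def family_of(self, species: str, gene: str) -> str | None:
        t = self.table
        hit = t[(t["species"] == species) & (t["gene_id"] == gene)]
        return None if hit.empty else str(hit["family"].iloc[0])


def read_tf_table(path: str | Path) -> TFTable:
    return TFTable(pd.read_csv(path, sep="\t", dtype=str))


def read_besthits(path: str | Path) -> pd.DataFrame:
    """Read the reference best-hit table.

    Columns: species, gene_id, ref_gene_id, function_terms (semicolon
    separated). Returns the frame with ``function_terms`` split into lists.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["function_terms"] = [
        [t.strip() for t in terms.split(";") if t.strip()]
        for terms in df["function_terms"]
    ]
    return df


# ---------------------------------------------------------------------------
# Sample similarity


def sample_similarity(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between all sample pairs of an expression matrix.

    Zero-variance samples are excluded with a warning. The result is a
    symmetric sample x sample matrix with unit diagonal.
    """
    values = expr.values
    if values.shape[1] < 2:
        raise ValueError("need at least two samples")
    sd = values.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(values.columns[~keep])
        warnings.warn(f"excluding zero-variance samples: {dropped}")
    kept = values.loc[:, keep]
    corr = np.corrcoef(kept.to_numpy(), rowvar=False)
    return pd.DataFrame(corr, index=kept.columns, columns=kept.columns)
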