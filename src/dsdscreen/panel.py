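"""Gene panel and shared domain vocabulary.

The screen operates on a fixed panel of 32 genes implicated in recessive
disorders of sex development (DSD) and central causes of hypogonadism (CHG),
grouped into three aetiological categories:

* ``GD``  — gonadal dysfunction (5 genes),
* ``HSA`` — disorders in hormone synthesis or action (19 genes, including the
  X-linked androgen receptor *AR*),
* ``CHG`` — central causes of hypogonadism (8 genes).

All genes are autosomal recessive except *AR*, which is X-linked recessive.
Coordinates are 1-based inclusive (VCF convention); the packaged fixture
carries placeholder intervals on the genes' real chromosomes — region logic
only ever depends on relative gene membership, never on absolute positions,
and a user-supplied panel TSV overrides the fixture.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Category",
    "Inheritance",
    "ClassLabel",
    "TierLabel",
    "GenePanelEntry",
    "GeneRegion",
    "load_panel",
    "write_panel",
    "panel_regions",
    "regions_to_bed",
    "CLINVAR_LABELS",
    "HGMD_LABELS",
    "LOF_CONSEQUENCES",
    "CONSEQUENCES",
]


class Category(str, enum.Enum):
    """Aetiological gene category."""

    GD = "GD"
    HSA = "HSA"
    CHG = "CHG"


class Inheritance(str, enum.Enum):
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    X_LINKED_RECESSIVE = "x_linked_recessive"


class ClassLabel(str, enum.Enum):
    """Five-class ACMG-style significance vocabulary (severity P > LP > VUS > LB > B)."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"

    @property
    def severity(self) -> int:
        return {"P": 4, "LP": 3, "VUS": 2, "LB": 1, "B": 0}[self.value]

    @property
    def is_plp(self) -> bool:
        return self in (ClassLabel.P, ClassLabel.LP)


class TierLabel(str, enum.Enum):
    """Evidence tier of a candidate pathogenic variant.

    A variant's label is its *first* (strictest) set; the sets have cumulative
    semantics when materialized as collections (SET1 ⊆ SET2 ⊆ SET3 ⊆ SET4).
    """

    SET1 = "SET1"
    SET2 = "SET2"
    SET3 = "SET3"
    SET4 = "SET4"
    NONE = "NONE"

    @property
    def rank(self) -> int:
        return {"SET1": 1, "SET2": 2, "SET3": 3, "SET4": 4, "NONE": 5}[self.value]


#: ClinVar-style significance tokens (clinical assertions; may be absent or conflicting).
CLINVAR_LABELS = frozenset({"P", "LP", "VUS", "LB", "B", "conflicting", "absent"})

#: HGMD-style class tokens; only the literal disease-causing "DM" is rescue-eligible.
HGMD_LABELS = frozenset({"DM", "other", "absent"})

#: Transcript consequence vocabulary; the first three are loss-of-function.
LOF_CONSEQUENCES = frozenset({"stop_gain", "frameshift", "splice"})
CONSEQUENCES = LOF_CONSEQUENCES | {"missense", "synonymous", "intronic", "intergenic", "other"}


@dataclass(frozen=True)
class GenePanelEntry:
    gene_symbol: str
    category: Category
    inheritance: Inheritance
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    mim: str = ""
    phenotype_mim: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"{self.gene_symbol}: empty chromosome")
        if self.start > self.end:
            raise ValueError(f"{self.gene_symbol}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class GeneRegion:
    """A flanked gene interval, 1-based inclusive, carrying its gene symbol."""

    gene_symbol: str
    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


_PANEL_COLUMNS = ["gene", "category", "inheritance", "chrom", "start", "end", "mim", "phenotype_mim"]


def _default_panel_path():
    return resources.files("dsdscreen.data") / "panel_32genes.tsv"


def load_panel(path: str | Path | None = None) -> list[GenePanelEntry]:
    """Load a gene panel TSV; with no argument, the packaged 32-gene fixture.

    Duplicate gene symbols, unknown category/inheritance tokens, and missing
    coordinates are hard errors naming the offending row.
    """
    source = _default_panel_path() if path is None else Path(path)
    with resources.as_file(source) if path is None else _noop(source) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    missing = [c for c in _PANEL_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"panel TSV missing columns: {missing}")
    entries: list[GenePanelEntry] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        gene = str(row["gene"])
        if gene in seen:
            raise ValueError(f"duplicate gene symbol {gene!r} at row {idx}")
        seen.add(gene)
        try:
            category = Category(row["category"])
        except ValueError:
            raise ValueError(f"row {idx} ({gene}): unknown category {row['category']!r}") from None
        try:
            inheritance = Inheritance(row["inheritance"])
        except ValueError:
            raise ValueError(
                f"row {idx} ({gene}): unknown inheritance {row['inheritance']!r}"
            ) from None
        if pd.isna(row["start"]) or pd.isna(row["end"]):
            raise ValueError(f"row {idx} ({gene}): missing coordinate")
        entries.append(
            GenePanelEntry(
                gene_symbol=gene,
                category=category,
                inheritance=inheritance,
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                mim="" if pd.isna(row.get("mim")) else str(row.get("mim", "")),
                phenotype_mim=""
                if pd.isna(row.get("phenotype_mim"))
                else str(row.get("phenotype_mim", "")),
            )
        )
    return entries


class _noop:
    """Context manager passing a path through (mirror of resources.as_file)."""

    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def write_panel(entries: Iterable[GenePanelEntry], path: str | Path) -> None:
    """Write entries to TSV in the canonical column order (round-trips with load_panel)."""
    df = pd.DataFrame(
        [
            {
                "gene": e.gene_symbol,
                "category": e.category.value,
                "inheritance": e.inheritance.value,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "mim": e.mim,
                "phenotype_mim": e.phenotype_mim,
            }
            for e in entries
        ],
        columns=_PANEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def panel_regions(entries: Sequence[GenePanelEntry], flank: int = 1000) -> list[GeneRegion]:
    """Flanked per-gene intervals: [start − flank, end + flank], clipped at 1.

    The default 1 kb flank captures promoter-proximal and UTR-adjacent variants
    around each gene.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    return [
        GeneRegion(
            gene_symbol=e.gene_symbol,
            chrom=e.chrom,
            start=max(1, e.start - flank),
            end=e.end + flank,
        )
        for e in entries
    ]


def regions_to_bed(regions: Sequence[GeneRegion], path: str | Path) -> None:
    """Export regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_symbol}\n")
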