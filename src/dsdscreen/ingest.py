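"""Variant ingestion: VCF reading, multiallelic splitting, QC filtering,
panel restriction and annotation joining.

The pipeline consumes a sites-only or genotyped VCF restricted to the panel,
splits multiallelic records into biallelic ones (per-allele AC carried over,
AN unchanged), removes records that failed variant-quality recalibration
(anything other than the literal ``PASS``), intersects with the flanked gene
regions, and joins an external annotation table supplying the three database
labels (ClinVar-like, InterVar-like ACMG class with criteria, HGMD-like) and
per-transcript consequences with expression weights.

Frequency semantics: the stored ``aaf`` is the alternate-allele frequency
``ac / an``. Reference-panel "MAF" columns in the wild can exceed 0.5; every
downstream threshold is applied to ``aaf``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .panel import CLINVAR_LABELS, CONSEQUENCES, HGMD_LABELS, ClassLabel, GeneRegion

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptConsequence",
    "AnnotatedVariant",
    "RawRecord",
    "read_vcf",
    "split_multiallelic",
    "vqsr_filter",
    "restrict_to_panel",
    "read_annotation_table",
    "join_annotations",
    "variants_to_frame",
]

MISSING_DOSAGE = -1


@dataclass(frozen=True)
class TranscriptConsequence:
    """Predicted consequence on one transcript isoform.

    ``expression_weight`` is the aggregate RNA-seq support for the transcript;
    the isoform with the greatest weight is the major transcript.
    """

    transcript_id: str
    consequence: str
    expression_weight: float

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.expression_weight < 0:
            raise ValueError("expression_weight must be >= 0")


@dataclass
class AnnotatedVariant:
    """One biallelic variant (post-splitting) with labels and consequences."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    filter_status: str = "PASS"
    an: int = 0
    ac: int = 0
    gene: str = ""
    clinvar: str = "absent"
    intervar: ClassLabel | None = None
    hgmd: str = "absent"
    acmg_criteria: frozenset[str] = frozenset()
    consequences: tuple[TranscriptConsequence, ...] = ()
    class_without_pvs1: ClassLabel | None = None
    dosages: np.ndarray | None = None  # per-individual alt-allele dosage, -1 = missing
    # set by tiers.demote_minor_isoform_lof
    ambiguous_lof: bool = False
    pvs1_removed: bool = False

    def __post_init__(self) -> None:
        if self.clinvar not in CLINVAR_LABELS:
            raise ValueError(f"{self.key}: unknown clinvar label {self.clinvar!r}")
        if self.hgmd not in HGMD_LABELS:
            raise ValueError(f"{self.key}: unknown hgmd label {self.hgmd!r}")
        if not 0 <= self.ac <= max(self.an, 0):
            raise ValueError(f"{self.key}: AC={self.ac} outside [0, AN={self.an}]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def aaf(self) -> float:
        """Alternate-allele frequency ac/an (nan when AN is 0)."""
        return self.ac / self.an if self.an > 0 else float("nan")


@dataclass(frozen=True)
class RawRecord:
    """A raw VCF record before allele splitting (possibly multiallelic)."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    filter_status: str
    an: int
    ac: tuple[int, ...]
    # allele index per chromosome per individual; shape (n_individuals, max_ploidy),
    # -1 = missing call, -2 = absent chromosome (haploid sample)
    allele_matrix: np.ndarray | None = None


def _as_tuple(value) -> tuple[int, ...]:
    if value is None:
        return ()
    if isinstance(value, (int, np.integer)):
        return (int(value),)
    return tuple(int(x) for x in value)


def read_vcf(path: str | Path, genotypes: bool = False) -> Iterator[RawRecord]:
    """Stream raw records from a VCF via cyvcf2.

    With ``genotypes=True`` the per-individual allele matrix is retained so a
    genotype census can be run downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    for v in vcf:
        allele_matrix = None
        if genotypes and len(vcf.samples) > 0:
            rows = []
            for g in v.genotypes:  # [a1, (a2,) phased_flag]
                alleles = list(g[:-1])
                while len(alleles) < 2:
                    alleles.append(-2)
                rows.append(alleles[:2])
            allele_matrix = np.asarray(rows, dtype=np.int8)
        yield RawRecord(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alts=tuple(v.ALT),
            filter_status=v.FILTER or "PASS",  # cyvcf2 reports PASS as None
            an=int(v.INFO.get("AN", 0) or 0),
            ac=_as_tuple(v.INFO.get("AC")),
            allele_matrix=allele_matrix,
        )


def split_multiallelic(record: RawRecord) -> list[AnnotatedVariant]:
    """Split a (possibly multiallelic) record into one biallelic variant per
    alternate allele.

    Each output's ``ac`` is its allele's count; ``an`` is unchanged, so the sum
    of the output allele counts equals the record's total alternate count.
    Dosages, when genotypes are present, count copies of the specific allele.
    """
    if len(record.alts) < 1:
        raise ValueError(f"{record.chrom}:{record.pos} has no alternate allele")
    if len(record.ac) != len(record.alts):
        raise ValueError(
            f"{record.chrom}:{record.pos}: AC array length {len(record.ac)} "
            f"!= number of alt alleles {len(record.alts)}"
        )
    if record.ref and len(record.ref) > 1 and any(
        len(a) > 1 and a[0] == record.ref[0] for a in record.alts
    ):
        # a shared leading base with both sides longer than one suggests an
        # untrimmed (non-left-normalized) indel representation
        logger.warning(
            "%s:%s ref/alt share a leading base; input may not be left-normalized",
            record.chrom,
            record.pos,
        )
    out = []
    for i, alt in enumerate(record.alts):
        dosages = None
        if record.allele_matrix is not None:
            m = record.allele_matrix
            dosages = (m == i + 1).sum(axis=1).astype(np.int16)
            dosages[(m == -1).any(axis=1)] = MISSING_DOSAGE
        out.append(
            AnnotatedVariant(
                chrom=record.chrom,
                pos=record.pos,
                ref=record.ref,
                alt=alt,
                filter_status=record.filter_status,
                an=record.an,
                ac=record.ac[i],
                dosages=dosages,
            )
        )
    return out


def vqsr_filter(
    variants: Iterable[AnnotatedVariant],
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Partition variants into (retained, removed) on FILTER status.

    Only the literal ``PASS`` is retained; every recalibration-tranche token
    (e.g. ``VQSRTrancheSNP99.50to99.60``) and any other non-PASS value is
    removed. Records with no filter status are removed and logged.
    """
    retained, removed = [], []
    for v in variants:
        if not v.filter_status:
            logger.warning("%s: missing filter status; treated as removed", v.key)
            removed.append(v)
        elif v.filter_status == "PASS":
            retained.append(v)
        else:
            removed.append(v)
    return retained, removed


def restrict_to_panel(
    variants: Iterable[AnnotatedVariant], regions: Sequence[GeneRegion]
) -> list[AnnotatedVariant]:
    """Keep variants inside at least one flanked gene region, tagging the gene.

    A variant inside two genes' regions is emitted once per gene (all
    downstream statistics are per-gene). Idempotent: output is a subset of
    (gene-tagged copies of) the input.
    """
    by_chrom: dict[str, list[GeneRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out = []
    for v in variants:
        regions_here = by_chrom.get(v.chrom, ())
        if v.gene:  # already gene-assigned: keep that assignment (idempotence)
            if any(r.gene_symbol == v.gene and r.start <= v.pos <= r.end for r in regions_here):
                out.append(v)
            continue
        for r in regions_here:
            if r.start <= v.pos <= r.end:
                out.append(replace(v, gene=r.gene_symbol))
    return out


_ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "clinvar", "intervar", "hgmd"]


def _parse_consequences(raw: str) -> tuple[TranscriptConsequence, ...]:
    if not raw or pd.isna(raw):
        return ()
    out = []
    for triple in str(raw).split(";"):
        if not triple.strip():
            continue
        tx, cons, weight = triple.split(":")
        out.append(TranscriptConsequence(tx, cons, float(weight)))
    return tuple(out)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read the annotation TSV keyed by (chrom, pos, ref, alt).

    Columns: chrom, pos, ref, alt, clinvar, intervar, hgmd, acmg_criteria
    (comma-joined), consequences (``transcript:consequence:weight`` triples,
    semicolon-joined), optional class_without_pvs1.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation TSV missing columns: {missing}")
    return df


def join_annotations(
    variants: Iterable[AnnotatedVariant], annotation: pd.DataFrame
) -> list[AnnotatedVariant]:
    """Attach database labels and consequences to variants by exact allele key.

    Unmatched variants fall back to ``clinvar=absent`` / ``hgmd=absent``; an
    InterVar-like class is mandatory for every variant (the tier classifier
    cannot act without one), so variants still lacking one after the join are
    a hard error listing the offending keys.
    """
    index: dict[tuple, dict] = {}
    for row in annotation.to_dict("records"):
        index[(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))] = row

    out, missing_intervar = [], []
    for v in variants:
        row = index.get(v.key)
        if row is None:
            # No annotation row: database labels default to absent, but the
            # classifier needs an ACMG class, so the variant must already carry one.
            if v.intervar is None:
                missing_intervar.append(v.key)
            else:
                out.append(replace(v, clinvar="absent", hgmd="absent"))
            continue
        criteria = row.get("acmg_criteria", "")
        criteria_set = (
            frozenset(c.strip() for c in str(criteria).split(",") if c.strip())
            if criteria and not pd.isna(criteria)
            else frozenset()
        )
        override = row.get("class_without_pvs1")
        if override is not None and not pd.isna(override) and str(override):
            override = ClassLabel(str(override))
        else:
            override = None
        if pd.isna(row.get("intervar")) or not str(row.get("intervar", "")):
            missing_intervar.append(v.key)
            continue
        clinvar = row.get("clinvar")
        hgmd = row.get("hgmd")
        out.append(
            replace(
                v,
                clinvar="absent" if pd.isna(clinvar) or not str(clinvar) else str(clinvar),
                intervar=ClassLabel(str(row["intervar"])),
                hgmd="absent" if pd.isna(hgmd) or not str(hgmd) else str(hgmd),
                acmg_criteria=criteria_set,
                consequences=_parse_consequences(row.get("consequences", "")),
                class_without_pvs1=override,
            )
        )
    if missing_intervar:
        raise ValueError(
            "variants lacking an InterVar-like class after annotation join: "
            f"{missing_intervar[:20]}{'...' if len(missing_intervar) > 20 else ''}"
        )
    return out


def variants_to_frame(variants: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    """Normalized per-variant table (one row per variant × gene assignment)."""
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "gene": [v.gene for v in variants],
            "filter": [v.filter_status for v in variants],
            "an": [v.an for v in variants],
            "ac": [v.ac for v in variants],
            "aaf": [v.aaf for v in variants],
            "clinvar": [v.clinvar for v in variants],
            "intervar": [v.intervar.value if v.intervar else "" for v in variants],
            "hgmd": [v.hgmd for v in variants],
            "acmg_criteria": [",".join(sorted(v.acmg_criteria)) for v in variants],
        }
    )
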