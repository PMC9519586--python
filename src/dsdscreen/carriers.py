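"""Carrier-frequency and biallelic-risk estimation under Hardy-Weinberg
equilibrium, plus a genotype-level census.

For each gene, the cumulative pathogenic allele frequency is

    Q = sum of the alternate-allele frequencies of its tiered variants,

excluding isoform-ambiguous variants. Under HWE the expected heterozygous
carrier frequency is 2(1-Q)Q and the biallelic-inactivation (BI) probability —
homozygote or compound heterozygote — is Q² for autosomal genes. For the
X-linked androgen receptor the convention used here reports the risk as Q/3
(the share of X chromosomes residing in males); the plain hemizygote rate Q is
available behind ``x_linked_mode="Q"``.

"1 in N" display figures use floor(1/f): a frequency of 3.41e-5 prints as
"1 in 29 thousand", 0.000436 as "1 in 2293".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import Category, GenePanelEntry, Inheritance, TierLabel
from .ingest import MISSING_DOSAGE, AnnotatedVariant
from .tiers import TierAssignment, tier_sets

__all__ = [
    "CarrierEstimate",
    "GenotypeCensus",
    "cumulative_q",
    "het_carrier_freq",
    "biallelic_risk",
    "one_in_n",
    "per_gene_estimates",
    "aggregate_by_category",
    "fold_changes",
    "cohort_carrier_fraction",
    "genotype_census",
]

_TIERS = (TierLabel.SET1, TierLabel.SET2, TierLabel.SET3, TierLabel.SET4)


@dataclass(frozen=True)
class CarrierEstimate:
    gene: str
    tier: TierLabel  # cumulative set
    q: float
    het_freq: float
    bi_risk: float
    one_in_n_carrier: int | None
    one_in_n_bi: int | None


@dataclass(frozen=True)
class GenotypeCensus:
    cohort_size: int
    het_carriers: dict[str, int]  # gene -> carrier count (dosage >= 1 anywhere)
    homozygotes: list[tuple[int, str, tuple]]  # (individual, gene, variant key)
    compound_hets: list[tuple[int, str, tuple, tuple]]  # (individual, gene, key1, key2)
    multi_gene_carriers: list[tuple[int, tuple[str, ...]]]  # (individual, genes)


def one_in_n(f: float) -> int:
    """floor(1/f) for a positive frequency (the display denominator)."""
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    return math.floor(1.0 / f)


def cumulative_q(
    gene: str,
    tier: TierLabel,
    assignments: Sequence[TierAssignment],
    variants: Sequence[AnnotatedVariant],
) -> float:
    """Cumulative pathogenic allele frequency for one gene at one tier.

    Sums aaf over the gene's variants whose first tier is at or above ``tier``;
    ambiguous (minor-isoform LOF) variants are excluded. Empty set → 0.
    """
    vmap = {(v.key, v.gene): v for v in variants}
    q = 0.0
    for a in assignments:
        if a.gene != gene or a.ambiguous or a.tier is TierLabel.NONE:
            continue
        if a.tier.rank <= tier.rank:
            v = vmap.get((a.key, a.gene)) or vmap.get((a.key, ""))
            if v is None:
                raise KeyError(f"no variant record for assignment {a.key}")
            q += v.aaf
    return q


def het_carrier_freq(q: float) -> float:
    """Expected heterozygous-carrier frequency 2(1-Q)Q under HWE."""
    if not 0 <= q <= 1:
        raise ValueError(f"Q must be in [0, 1], got {q}")
    return 2.0 * (1.0 - q) * q


def biallelic_risk(q: float, inheritance: Inheritance | str, x_linked_mode: str = "Q/3") -> float:
    """Biallelic-inactivation probability: Q² autosomal, Q/3 X-linked.

    ``x_linked_mode="Q"`` switches the X-linked convention to the plain male
    hemizygote frequency Q.
    """
    if not 0 <= q <= 1:
        raise ValueError(f"Q must be in [0, 1], got {q}")
    inheritance = Inheritance(inheritance)
    if inheritance is Inheritance.AUTOSOMAL_RECESSIVE:
        return q * q
    if x_linked_mode == "Q/3":
        return q / 3.0
    if x_linked_mode == "Q":
        return q
    raise ValueError(f"unknown x_linked_mode {x_linked_mode!r}")


def per_gene_estimates(
    assignments: Sequence[TierAssignment],
    variants: Sequence[AnnotatedVariant],
    panel: Sequence[GenePanelEntry],
    x_linked_mode: str = "Q/3",
) -> pd.DataFrame:
    """Per-gene × per-tier Q, carrier and BI estimates (long format)."""
    rows = []
    for entry in panel:
        gene_vars = [v for v in variants if v.gene == entry.gene_symbol]
        gene_assign = [a for a in assignments if a.gene == entry.gene_symbol]
        for tier in _TIERS:
            q = cumulative_q(entry.gene_symbol, tier, gene_assign, gene_vars)
            het = het_carrier_freq(q)
            bi = biallelic_risk(q, entry.inheritance, x_linked_mode=x_linked_mode)
            rows.append(
                {
                    "gene": entry.gene_symbol,
                    "category": entry.category.value,
                    "inheritance": entry.inheritance.value,
                    "tier": tier.value,
                    "q": q,
                    "het_freq": het,
                    "bi_risk": bi,
                    "one_in_n_carrier": one_in_n(het) if het > 0 else None,
                    "one_in_n_bi": one_in_n(bi) if bi > 0 else None,
                }
            )
    return pd.DataFrame(rows)


def aggregate_by_category(
    per_gene: pd.DataFrame, panel: Sequence[GenePanelEntry]
) -> pd.DataFrame:
    """Category × tier biallelic-risk summary.

    Category cells sum per-gene Q² over the category's *autosomal* genes
    (per-gene risks are summed, not a pooled-Q square). The X-linked gene is
    reported as its own ``AR`` row and excluded from ``Total``.
    """
    x_genes = {e.gene_symbol for e in panel if e.inheritance is Inheritance.X_LINKED_RECESSIVE}
    tiers = [t.value for t in _TIERS]
    out = {}
    for cat in (Category.GD, Category.HSA, Category.CHG):
        sub = per_gene[
            (per_gene["category"] == cat.value) & (~per_gene["gene"].isin(x_genes))
        ]
        out[cat.value] = [sub.loc[sub["tier"] == t, "bi_risk"].sum() for t in tiers]
    sub = per_gene[per_gene["gene"].isin(x_genes)]
    out["AR"] = [sub.loc[sub["tier"] == t, "bi_risk"].sum() for t in tiers]
    df = pd.DataFrame(out, index=pd.Index(tiers, name="tier")).T
    df.loc["Total"] = df.loc[["GD", "HSA", "CHG"]].sum()
    df.index.name = "category"
    return df


def fold_changes(summary: pd.DataFrame) -> pd.DataFrame:
    """Fold change between consecutive tiers per category row (nan where the
    earlier tier is zero)."""
    cols = list(summary.columns)
    out = {}
    for prev, nxt in zip(cols, cols[1:]):
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"{nxt}/{prev}"] = np.where(
                summary[prev] > 0, summary[nxt] / summary[prev], np.nan
            )
    return pd.DataFrame(out, index=summary.index)


def cohort_carrier_fraction(q_by_gene: Mapping[str, float]) -> dict[str, float]:
    """Cohort-wide carrier fraction, in two conventions.

    ``pooled``: 2(1-Q_tot)Q_tot with Q_tot the sum of per-gene Qs — treats all
    pathogenic alleles as one locus. ``product``: 1 - Π_g(1 - 2Q_g(1-Q_g)) —
    probability of carrying at least one pathogenic allele under independent
    genes. Both are reported; they coincide for a single gene and diverge only
    at second order in the Qs.
    """
    q_tot = float(sum(q_by_gene.values()))
    pooled = het_carrier_freq(q_tot) if q_tot <= 1 else float("nan")
    prod = 1.0
    for q in q_by_gene.values():
        prod *= 1.0 - het_carrier_freq(q)
    product = 1.0 - prod
    return {
        "q_total": q_tot,
        "pooled": pooled,
        "pooled_one_in_n": one_in_n(pooled) if pooled > 0 else None,
        "product": product,
        "product_one_in_n": one_in_n(product) if product > 0 else None,
    }


def genotype_census(
    dosages: np.ndarray,
    variant_meta: Sequence[tuple[tuple, str]],
    tiered_keys: Iterable[tuple],
) -> GenotypeCensus:
    """Census of carrier genotypes over a dosage matrix.

    ``dosages`` is (n_variants, n_individuals) with values {0, 1, 2} or -1 for
    missing; ``variant_meta`` aligns rows to (variant key, gene). Homozygote:
    dosage 2 at a tiered variant. Compound het: two distinct tiered variants of
    one gene with dosage ≥ 1 in one individual (unphased — assumed trans).
    Multi-gene carrier: tiered dosage ≥ 1 in ≥ 2 genes.
    """
    dosages = np.asarray(dosages)
    valid = {0, 1, 2, MISSING_DOSAGE}
    bad = set(np.unique(dosages)) - valid
    if bad:
        raise ValueError(f"dosages outside {{0,1,2,missing}}: {sorted(bad)}")
    if dosages.shape[0] != len(variant_meta):
        raise ValueError("dosage rows do not match variant_meta")
    tiered = set(tiered_keys)
    n_ind = dosages.shape[1] if dosages.ndim == 2 else 0

    het_carriers: dict[str, set[int]] = {}
    homozygotes: list[tuple[int, str, tuple]] = []
    compound_hets: list[tuple[int, str, tuple, tuple]] = []
    per_ind_gene_vars: dict[tuple[int, str], list[tuple]] = {}

    for row, (key, gene) in enumerate(variant_meta):
        if key not in tiered:
            continue
        d = dosages[row]
        for ind in np.nonzero(d >= 1)[0]:
            ind = int(ind)
            het_carriers.setdefault(gene, set()).add(ind)
            per_ind_gene_vars.setdefault((ind, gene), []).append(key)
            if d[ind] == 2:
                homozygotes.append((ind, gene, key))

    for (ind, gene), keys in sorted(per_ind_gene_vars.items()):
        if len(keys) >= 2:
            keys = sorted(keys)
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    compound_hets.append((ind, gene, keys[i], keys[j]))

    genes_by_ind: dict[int, set[str]] = {}
    for (ind, gene) in per_ind_gene_vars:
        genes_by_ind.setdefault(ind, set()).add(gene)
    multi = [
        (ind, tuple(sorted(genes))) for ind, genes in sorted(genes_by_ind.items()) if len(genes) >= 2
    ]

    return GenotypeCensus(
        cohort_size=n_ind,
        het_carriers={g: len(s) for g, s in sorted(het_carriers.items())},
        homozygotes=sorted(homozygotes),
        compound_hets=sorted(compound_hets),
        multi_gene_carriers=multi,
    )
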