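"""Evidence-tier classification of candidate pathogenic variants.

Each PASS variant is assigned to nested evidence tiers driven by its ACMG
(InterVar-like) class and corroborated by clinical-database labels:

* **Set 1** — ACMG P/LP *and* ClinVar P/LP (most conservative);
* **Set 2** — all ACMG P/LP (Set 1 plus ACMG-only calls);
* **Set 3** — Set 2 plus ACMG-VUS variants asserted P/LP in ClinVar;
* **Set 4** — Set 3 plus remaining ACMG-VUS variants that are HGMD
  disease-causing (DM).

VUS rescue (Sets 3/4) additionally requires alternate-allele frequency below
0.03 — common alleles are not credible recessive-disease candidates. ACMG
P/LP variants are not gated on frequency (in practice they all pass it); a
violation is logged rather than enforced.

Loss-of-function calls that touch only a *minor* transcript isoform while the
major (highest RNA-seq support) isoform is untouched (intronic/intergenic/
other) are demoted: the PVS1 very-strong criterion is withdrawn, the variant
is flagged ambiguous, and an ACMG class owed solely to PVS1 falls back to VUS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .panel import LOF_CONSEQUENCES, ClassLabel, TierLabel
from .ingest import AnnotatedVariant

logger = logging.getLogger(__name__)

__all__ = ["TierAssignment", "assign_tier", "demote_minor_isoform_lof", "tier_sets", "tier_count_matrix"]

#: Reason codes attached to assignments (machine-readable audit trail).
REASONS = frozenset(
    {"INTERVAR_PLP", "CLINVAR_PLP", "HGMD_DM", "MAF_FAIL", "MINOR_ISOFORM_LOF", "PVS1_REMOVED"}
)


@dataclass(frozen=True)
class TierAssignment:
    key: tuple[str, int, str, str]
    gene: str
    tier: TierLabel
    ambiguous: bool = False
    reasons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = self.reasons - REASONS
        if unknown:
            raise ValueError(f"unknown reason codes: {sorted(unknown)}")


def assign_tier(v: AnnotatedVariant, maf_threshold: float = 0.03) -> TierAssignment:
    """Assign a variant its first (strictest) evidence tier.

    Decision order:

    1. ACMG P/LP → SET1 if ClinVar P/LP, else SET2;
    2. ACMG VUS with aaf < ``maf_threshold`` → SET3 if ClinVar P/LP, else SET4
       if HGMD DM, else NONE;
    3. everything else (LB/B, or VUS failing the frequency filter) → NONE.

    ClinVar "conflicting" does not count as P/LP; HGMD classes other than the
    literal DM are not rescue-eligible.
    """
    if v.intervar is None:
        raise ValueError(f"{v.key}: no ACMG class; cannot classify")
    reasons: set[str] = set()
    clinvar_plp = v.clinvar in ("P", "LP")
    if clinvar_plp:
        reasons.add("CLINVAR_PLP")
    if v.hgmd == "DM":
        reasons.add("HGMD_DM")

    if v.intervar.is_plp:
        reasons.add("INTERVAR_PLP")
        aaf = v.aaf
        if aaf == aaf and aaf >= maf_threshold:  # nan-safe
            logger.warning(
                "%s: ACMG %s variant with aaf %.4g >= %.4g (kept; frequency filter "
                "applies only to VUS rescue)",
                v.key,
                v.intervar.value,
                aaf,
                maf_threshold,
            )
        tier = TierLabel.SET1 if clinvar_plp else TierLabel.SET2
    elif v.intervar is ClassLabel.VUS:
        aaf = v.aaf
        if aaf != aaf:
            raise ValueError(f"{v.key}: undefined aaf; frequency filter cannot be evaluated")
        if aaf >= maf_threshold:
            reasons.add("MAF_FAIL")
            tier = TierLabel.NONE
        elif clinvar_plp:
            tier = TierLabel.SET3
        elif v.hgmd == "DM":
            tier = TierLabel.SET4
        else:
            tier = TierLabel.NONE
    else:  # LB or B
        tier = TierLabel.NONE

    if v.ambiguous_lof:
        reasons.add("MINOR_ISOFORM_LOF")
        if v.pvs1_removed:
            reasons.add("PVS1_REMOVED")
    return TierAssignment(
        key=v.key, gene=v.gene, tier=tier, ambiguous=v.ambiguous_lof, reasons=frozenset(reasons)
    )


def demote_minor_isoform_lof(v: AnnotatedVariant) -> AnnotatedVariant:
    """Withdraw PVS1 when a loss-of-function call rests only on minor isoforms.

    The major transcript is the one with the greatest expression weight (ties:
    all tied transcripts are major, and an LOF on any of them blocks demotion —
    the conservative choice). If every LOF consequence sits on a non-major
    transcript while every major transcript is merely intronic/intergenic/other,
    the variant is flagged ambiguous, PVS1 is removed, and — unless the
    annotation supplies an explicit PVS1-free reclassification — an ACMG P/LP
    class collapses to VUS, since no full ACMG recombination engine is run here.

    Never raises severity and never adds criteria.
    """
    if not v.consequences:
        raise ValueError(f"{v.key}: no transcript consequences; cannot assess isoforms")
    max_weight = max(c.expression_weight for c in v.consequences)
    major = [c for c in v.consequences if c.expression_weight == max_weight]
    minor = [c for c in v.consequences if c.expression_weight < max_weight]

    lof_on_minor = any(c.consequence in LOF_CONSEQUENCES for c in minor)
    lof_on_major = any(c.consequence in LOF_CONSEQUENCES for c in major)
    major_untouched = all(c.consequence in ("intronic", "intergenic", "other") for c in major)

    if not (lof_on_minor and not lof_on_major and major_untouched):
        return v

    criteria = v.acmg_criteria
    intervar = v.intervar
    pvs1_removed = False
    if "PVS1" in criteria:
        criteria = criteria - {"PVS1"}
        pvs1_removed = True
        if intervar is not None and intervar.is_plp:
            intervar = v.class_without_pvs1 if v.class_without_pvs1 is not None else ClassLabel.VUS
    return replace(
        v, acmg_criteria=criteria, intervar=intervar, ambiguous_lof=True, pvs1_removed=pvs1_removed
    )


def tier_sets(assignments: list[TierAssignment]) -> dict[TierLabel, list[TierAssignment]]:
    """Materialize the cumulative tier collections SET1 ⊆ SET2 ⊆ SET3 ⊆ SET4.

    Ambiguous assignments are retained here (count reports keep them, flagged);
    frequency totals downstream exclude them.
    """
    out: dict[TierLabel, list[TierAssignment]] = {
        TierLabel.SET1: [],
        TierLabel.SET2: [],
        TierLabel.SET3: [],
        TierLabel.SET4: [],
    }
    for a in assignments:
        if a.tier is TierLabel.NONE:
            continue
        for tier in out:
            if a.tier.rank <= tier.rank:
                out[tier].append(a)
    return out


def tier_count_matrix(assignments: list[TierAssignment], genes: list[str] | None = None):
    """Per-gene × per-set cumulative count matrix (evidence-tier census table).

    Rows are genes (all panel genes when ``genes`` is given, so zero rows are
    visible), columns SET1..SET4.
    """
    import pandas as pd

    sets = tier_sets(assignments)
    gene_order = genes if genes is not None else sorted({a.gene for a in assignments})
    data = {}
    for tier, members in sets.items():
        counts: dict[str, int] = {g: 0 for g in gene_order}
        for a in members:
            if a.gene in counts:
                counts[a.gene] += 1
        data[tier.value.lower()] = [counts[g] for g in gene_order]
    return pd.DataFrame(data, index=pd.Index(gene_order, name="gene"))
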