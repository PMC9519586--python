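"""End-to-end orchestration and report rendering.

Stage order mirrors the screen's filtering funnel: ingest (split, QC filter,
panel restriction, annotation join) → platform-bias screen → isoform demotion
→ tier classification → carrier statistics → genotype census →
haploinsufficiency comparison. Every intermediate table is written to the
output directory together with a machine-readable run manifest recording
inputs, thresholds, seed and stage-by-stage counts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bias as bias_mod
from . import carriers as carriers_mod
from . import hi as hi_mod
from . import ingest as ingest_mod
from . import tiers as tiers_mod
from .panel import TierLabel, load_panel, panel_regions

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "format_one_in_n", "sci3"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the screen's thresholds
    (VUS-rescue frequency < 0.03, bias alpha 0.001, 1 kb flanks, Q/3 for the
    X-linked gene)."""

    vcf: str
    annotation: str
    out_dir: str
    panel: str | None = None
    platform_counts: str | None = None
    hi_scores: str | None = None
    maf_threshold: float = 0.03
    bias_alpha: float = 0.001
    flank: int = 1000
    x_linked_mode: str = "Q/3"
    genotypes: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def format_one_in_n(f: float, thousands: bool = False) -> str:
    """Render a frequency as "1 in N" with N = floor(1/f).

    With ``thousands=True``, denominators of at least 1000 are floored to
    whole thousands ("1 in 29 thousand").
    """
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    n = math.floor(1.0 / f)
    if thousands and n >= 1000:
        return f"1 in {n // 1000} thousand"
    return f"1 in {n}"


def sci3(x: float) -> str:
    """Scientific notation at 3 significant figures ("8.49E-06" style)."""
    return f"{x:.2E}"


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the report bundle (tables + funnel counts).

    Any stage failure propagates with the stage name prepended so the
    offending inputs are identifiable.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    funnel: dict[str, int] = {}
    bundle: dict = {"funnel": funnel}

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    # ---- ingest ----------------------------------------------------------
    name = stage("ingest")
    try:
        panel = load_panel(config.panel)
        regions = panel_regions(panel, flank=config.flank)
        raw = list(ingest_mod.read_vcf(config.vcf, genotypes=config.genotypes))
        funnel["vcf_records"] = len(raw)
        split = [v for r in raw for v in ingest_mod.split_multiallelic(r)]
        funnel["biallelic_variants"] = len(split)
        retained, removed = ingest_mod.vqsr_filter(split)
        funnel["pass"] = len(retained)
        funnel["vqsr_removed"] = len(removed)
        in_panel = ingest_mod.restrict_to_panel(retained, regions)
        funnel["in_panel"] = len(in_panel)
        annotation = ingest_mod.read_annotation_table(config.annotation)
        variants = ingest_mod.join_annotations(in_panel, annotation)
        removed_df = ingest_mod.variants_to_frame(removed)
        removed_df.to_csv(out_dir / "removed_variants.tsv", sep="\t", index=False)
    except Exception as e:
        raise RuntimeError(f"stage {name} failed: {e}") from e

    # ---- platform-bias screen -------------------------------------------
    name = stage("platform_bias")
    try:
        if config.platform_counts:
            counts = bias_mod.read_platform_table(config.platform_counts)
            _, biased_keys = bias_mod.screen_platform_bias(
                counts, alpha=config.bias_alpha, seed=config.seed
            )
            biased = set(biased_keys)
            bias_mod.platform_counts_frame(counts).to_csv(
                out_dir / "platform_bias.tsv", sep="\t", index=False
            )
            n_before = len(variants)
            variants = [v for v in variants if _vkey(v) not in biased]
            funnel["platform_biased_removed"] = n_before - len(variants)
        else:
            funnel["platform_biased_removed"] = 0
        funnel["unbiased"] = len(variants)
    except Exception as e:
        raise RuntimeError(f"stage {name} failed: {e}") from e

    # ---- demotion + tiering ---------------------------------------------
    name = stage("tier_classification")
    try:
        demoted = [
            tiers_mod.demote_minor_isoform_lof(v) if v.consequences else v for v in variants
        ]
        assignments = [tiers_mod.assign_tier(v, config.maf_threshold) for v in demoted]
        sets = tiers_mod.tier_sets(assignments)
        for tier, members in sets.items():
            funnel[f"tier_{tier.value.lower()}"] = len(members)
        funnel["ambiguous"] = sum(a.ambiguous for a in assignments)
        adf = pd.DataFrame(
            {
                "chrom": [a.key[0] for a in assignments],
                "pos": [a.key[1] for a in assignments],
                "ref": [a.key[2] for a in assignments],
                "alt": [a.key[3] for a in assignments],
                "gene": [a.gene for a in assignments],
                "first_tier": [a.tier.value for a in assignments],
                "ambiguous": [a.ambiguous for a in assignments],
                "reasons": [",".join(sorted(a.reasons)) for a in assignments],
            }
        )
        for tier in (TierLabel.SET1, TierLabel.SET2, TierLabel.SET3, TierLabel.SET4):
            member_keys = {(a.key, a.gene) for a in sets[tier]}
            adf[f"in_{tier.value.lower()}"] = [
                (k, g) in member_keys for k, g in zip(zip(adf.chrom, adf.pos, adf.ref, adf.alt), adf.gene)
            ]
        adf.to_csv(out_dir / "tier_assignments.tsv", sep="\t", index=False)
        gene_order = [e.gene_symbol for e in panel]
        count_matrix = tiers_mod.tier_count_matrix(assignments, genes=gene_order)
        count_matrix.to_csv(out_dir / "tier_counts.tsv", sep="\t")
        bundle["tier_counts"] = count_matrix
        bundle["assignments"] = assignments
    except Exception as e:
        raise RuntimeError(f"stage {name} failed: {e}") from e

    # ---- carrier statistics ---------------------------------------------
    name = stage("carrier_stats")
    try:
        per_gene = carriers_mod.per_gene_estimates(
            assignments, demoted, panel, x_linked_mode=config.x_linked_mode
        )
        per_gene.to_csv(out_dir / "per_gene_estimates.tsv", sep="\t", index=False)
        summary = carriers_mod.aggregate_by_category(per_gene, panel)
        summary_disp = summary.map(sci3)
        summary_disp.to_csv(out_dir / "category_summary.tsv", sep="\t")
        folds = carriers_mod.fold_changes(summary)
        folds.to_csv(out_dir / "category_fold_changes.tsv", sep="\t")
        carrier_rows = []
        for tier in ("SET1", "SET2", "SET3", "SET4"):
            q_by_gene = {
                g: float(per_gene.loc[(per_gene.gene == g) & (per_gene.tier == tier), "q"].iloc[0])
                for g in per_gene.gene.unique()
            }
            cc = carriers_mod.cohort_carrier_fraction(q_by_gene)
            cc["tier"] = tier
            cc["pooled_display"] = (
                format_one_in_n(cc["pooled"]) if cc["pooled"] and cc["pooled"] > 0 else ""
            )
            carrier_rows.append(cc)
        carrier_df = pd.DataFrame(carrier_rows)
        carrier_df.to_csv(out_dir / "carrier_summary.tsv", sep="\t", index=False)
        bundle["per_gene"] = per_gene
        bundle["category_summary"] = summary
        bundle["fold_changes"] = folds
        bundle["carrier_summary"] = carrier_df
    except Exception as e:
        raise RuntimeError(f"stage {name} failed: {e}") from e

    # ---- genotype census -------------------------------------------------
    name = stage("genotype_census")
    try:
        if config.genotypes and any(v.dosages is not None for v in demoted):
            meta = [(v.key, v.gene) for v in demoted]
            import numpy as np

            dosage_matrix = np.vstack(
                [
                    v.dosages if v.dosages is not None else np.zeros(0, dtype=np.int16)
                    for v in demoted
                ]
            )
            tiered_keys = {
                a.key for a in assignments if a.tier is not TierLabel.NONE and not a.ambiguous
            }
            census = carriers_mod.genotype_census(dosage_matrix, meta, tiered_keys)
            bundle["census"] = census
            census_df = pd.DataFrame(
                [
                    {"kind": "homozygote", "individual": i, "gene": g, "detail": str(k)}
                    for i, g, k in census.homozygotes
                ]
                + [
                    {
                        "kind": "compound_het_unphased",
                        "individual": i,
                        "gene": g,
                        "detail": f"{k1}|{k2}",
                    }
                    for i, g, k1, k2 in census.compound_hets
                ]
                + [
                    {
                        "kind": "multi_gene_carrier",
                        "individual": i,
                        "gene": ",".join(genes),
                        "detail": "",
                    }
                    for i, genes in census.multi_gene_carriers
                ]
            )
            census_df.to_csv(out_dir / "census.tsv", sep="\t", index=False)
            funnel["homozygotes"] = len(census.homozygotes)
            funnel["compound_hets"] = len(census.compound_hets)
            funnel["multi_gene_carriers"] = len(census.multi_gene_carriers)
    except Exception as e:
        raise RuntimeError(f"stage {name} failed: {e}") from e

    # ---- haploinsufficiency ---------------------------------------------
    name = stage("haploinsufficiency")
    try:
        if config.hi_scores:
            scores = hi_mod.read_scores(config.hi_scores)
            grouped = hi_mod.group_scores(scores, panel)
            rows = []
            for score, groups in grouped.items():
                for cat, vec in groups.items():
                    if len(vec):
                        mn, q25, med, q75, mx = hi_mod.box_stats(vec)
                        rows.append(
                            {
                                "score": score,
                                "category": cat,
                                "n": len(vec),
                                "min": mn,
                                "q25": q25,
                                "median": med,
                                "q75": q75,
                                "max": mx,
                            }
                        )
            hi_summary = pd.DataFrame(rows)
            hi_tests = pd.concat(
                [
                    hi_mod.pairwise_tests(groups).assign(score=score)
                    for score, groups in grouped.items()
                ],
                ignore_index=True,
            )
            hi_summary.to_csv(out_dir / "hi_summary.tsv", sep="\t", index=False)
            hi_tests.to_csv(out_dir / "hi_tests.tsv", sep="\t", index=False)
            hi_mod.plot_scores(grouped, out_dir / "hi_boxplot.png")
            bundle["hi_summary"] = hi_summary
            bundle["hi_tests"] = hi_tests
    except Exception as e:
        raise RuntimeError(f"stage {name} failed: {e}") from e

    manifest = {
        "config": asdict(config),
        "funnel": funnel,
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("funnel: %s", funnel)
    return bundle


def _vkey(v) -> str:
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"
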