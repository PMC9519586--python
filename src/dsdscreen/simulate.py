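"""Synthetic cohort generator.

Emulates the inputs of a reference-panel screen so every pipeline stage is
testable without any external download: a cohort VCF with Hardy-Weinberg
genotypes (haploid X for simulated males), an annotation table whose database
labels imply known true evidence tiers, platform allele-count tables with
injected frequency distortions, transcript models with minor-isoform LOF
traps, and haploinsufficiency score tables.

Defaults emulate the study conditions at reduced scale: 32 panel genes × 30
variants per gene × 2000 diploid individuals (the real panel held 8380), a
label mixture following the reported five-class proportions (P/LP/VUS/LB/B =
13/29/43856/445/5279 of 49,622 — pathogenic calls are rare), allele
frequencies drawn mostly from the rare end (log-uniform 1e-4..0.01, with a
10% common tail up to 0.5), 5% multiallelic sites, 2% quality-tranche
failures, and three minor-isoform LOF traps (the study flagged exactly three
ambiguous variants).

Everything is driven by one integer seed; regenerating with the same seed and
parameters is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import GenePanelEntry, Inheritance, load_panel

__all__ = [
    "LabelMixture",
    "SyntheticTruth",
    "SyntheticCohort",
    "decision_table_tier",
    "default_aaf_sampler",
    "generate_cohort",
    "inject_platform_bias",
    "make_isoform_trap",
    "generate_hi_scores",
]

TRANCHE_SNP = "VQSRTrancheSNP99.50to99.60"
TRANCHE_INDEL = "VQSRTrancheINDEL99.00to99.90"

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class LabelMixture:
    """Marginal label probabilities for the three databases.

    Defaults follow the five-class proportions observed in the reference
    screen; tests that need pathogenic-rich cohorts pass an enriched mixture.
    """

    intervar: dict = field(
        default_factory=lambda: {
            "P": 13 / 49622,
            "LP": 29 / 49622,
            "VUS": 43856 / 49622,
            "LB": 445 / 49622,
            "B": 5279 / 49622,
        }
    )
    clinvar: dict = field(
        default_factory=lambda: {
            "P": 0.003,
            "LP": 0.003,
            "VUS": 0.02,
            "LB": 0.005,
            "B": 0.01,
            "conflicting": 0.004,
            "absent": 0.955,
        }
    )
    hgmd: dict = field(default_factory=lambda: {"DM": 0.005, "other": 0.005, "absent": 0.99})

    def validate(self) -> None:
        for name, probs in (
            ("intervar", self.intervar),
            ("clinvar", self.clinvar),
            ("hgmd", self.hgmd),
        ):
            total = sum(probs.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"{name} mixture weights sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} mixture has negative weight")


def decision_table_tier(
    intervar: str, clinvar: str, hgmd: str, aaf: float, maf_threshold: float = 0.03
) -> str:
    """True evidence tier implied by a label combination.

    Literal transcription of the set definitions, kept deliberately separate
    from the production classifier so generated truth is an independent
    reference: Set 1 = ACMG P/LP corroborated by ClinVar P/LP; Set 2 = all
    ACMG P/LP; Set 3 adds ClinVar-P/LP VUS below the frequency threshold;
    Set 4 adds HGMD-DM VUS below the threshold.
    """
    plp = ("P", "LP")
    if intervar in plp:
        return "SET1" if clinvar in plp else "SET2"
    if intervar == "VUS" and aaf < maf_threshold:
        if clinvar in plp:
            return "SET3"
        if hgmd == "DM":
            return "SET4"
    return "NONE"


def default_aaf_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    """Allele-frequency spectrum: 90% rare (log-uniform 1e-4..0.01), 10%
    common (log-uniform 0.01..0.5)."""
    common = rng.random(size) < 0.10
    lo = np.where(common, np.log10(0.01), np.log10(1e-4))
    hi = np.where(common, np.log10(0.5), np.log10(0.01))
    return 10 ** (lo + rng.random(size) * (hi - lo))


@dataclass
class SyntheticTruth:
    """Generator ledger: per-variant truth and per-gene true Q for recovery tests."""

    seed: int
    n_individuals: int
    variants: pd.DataFrame  # chrom,pos,ref,alt,gene,true_tier,true_aaf,ambiguous,filtered
    q_per_gene: dict  # gene -> {SET1..SET4 -> true cumulative Q}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "n_individuals": self.n_individuals,
            "variants": self.variants.to_dict("records"),
            "q_per_gene": self.q_per_gene,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticCohort:
    vcf_path: Path | None
    annotation_path: Path | None
    truth: SyntheticTruth
    sites: pd.DataFrame  # one row per biallelic variant, aligned with dosage rows
    dosages: np.ndarray | None  # (n_variants, n_individuals), -1 missing
    sex: np.ndarray | None  # 1 = male, 0 = female


def _consequence_for(rng: np.random.Generator, intervar: str) -> tuple[str, bool]:
    """(consequence on the single major transcript, carries PVS1)."""
    if intervar in ("P", "LP"):
        cons = rng.choice(["stop_gain", "frameshift", "splice", "missense"], p=[0.3, 0.2, 0.1, 0.4])
        return str(cons), cons in ("stop_gain", "frameshift", "splice")
    cons = rng.choice(["missense", "synonymous", "intronic"], p=[0.5, 0.2, 0.3])
    return str(cons), False


def _truth_q(variants: pd.DataFrame) -> dict:
    """Per-gene cumulative true Q per tier, excluding ambiguous/filtered variants."""
    order = {"SET1": 1, "SET2": 2, "SET3": 3, "SET4": 4}
    out: dict[str, dict[str, float]] = {}
    for gene, grp in variants.groupby("gene", sort=True):
        ok = grp[(~grp["ambiguous"]) & (~grp["filtered"]) & (grp["true_tier"] != "NONE")]
        out[gene] = {
            tier: float(ok.loc[[order[t] <= rank for t in ok["true_tier"]], "true_aaf"].sum())
            for tier, rank in order.items()
        }
    return out


def generate_cohort(
    panel: Sequence[GenePanelEntry] | None = None,
    n_individuals: int = 2000,
    variants_per_gene: int = 30,
    aaf_sampler=default_aaf_sampler,
    label_mixture: LabelMixture | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    multiallelic_fraction: float = 0.05,
    nonpass_fraction: float = 0.02,
    n_isoform_traps: int = 3,
    sites_only: bool = False,
    maf_threshold: float = 0.03,
) -> SyntheticCohort:
    """Generate a labelled synthetic cohort for the full pipeline.

    Genotypes are drawn under HWE: each chromosome of an individual (one for
    simulated males at the X-linked gene) carries one of the record's alleles
    with its site frequency, independently across records — no linkage
    disequilibrium or population structure. A ``multiallelic_fraction`` of
    sites is merged into multiallelic VCF records (split again by ingestion),
    a ``nonpass_fraction`` receives quality-tranche FILTER strings, and
    ``n_isoform_traps`` variants carry their LOF consequence only on a minor
    transcript isoform (truth flags them ambiguous; their true tier is
    computed as if PVS1 were withdrawn). With ``out_dir`` set, a VCF and an
    annotation TSV are written; in-memory tables are always returned.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    panel = list(panel) if panel is not None else load_panel()
    mixture = label_mixture or LabelMixture()
    mixture.validate()
    rng = np.random.default_rng(seed)

    sex = rng.integers(0, 2, size=n_individuals).astype(np.int8)  # 1 = male
    n_male = int((sex == 1).sum())

    # ---- phase 1: site metadata ------------------------------------------
    rows = []
    for entry in panel:
        x_linked = entry.inheritance is Inheritance.X_LINKED_RECESSIVE
        span = entry.end - entry.start + 1
        n_pos = min(variants_per_gene, span)
        positions = np.sort(rng.choice(span, size=n_pos, replace=False)) + entry.start
        aafs = aaf_sampler(rng, n_pos)
        iv_keys, iv_p = zip(*mixture.intervar.items())
        cv_keys, cv_p = zip(*mixture.clinvar.items())
        hg_keys, hg_p = zip(*mixture.hgmd.items())
        intervars = rng.choice(iv_keys, size=n_pos, p=iv_p)
        clinvars = rng.choice(cv_keys, size=n_pos, p=cv_p)
        hgmds = rng.choice(hg_keys, size=n_pos, p=hg_p)
        for i in range(n_pos):
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + 1 + int(rng.integers(0, 3))) % 4
            is_indel = rng.random() < 0.1
            ref = _BASES[ref_i] + (_BASES[int(rng.integers(0, 4))] if is_indel else "")
            alt = _BASES[alt_i] if not is_indel else ref[0]
            cons, pvs1 = _consequence_for(rng, str(intervars[i]))
            rows.append(
                {
                    "chrom": entry.chrom,
                    "pos": int(positions[i]),
                    "ref": ref,
                    "alt": alt,
                    "gene": entry.gene_symbol,
                    "x_linked": x_linked,
                    "target_aaf": float(aafs[i]),
                    "intervar": str(intervars[i]),
                    "clinvar": str(clinvars[i]),
                    "hgmd": str(hgmds[i]),
                    "pvs1": bool(pvs1),
                    "consequences": f"TX_{entry.gene_symbol}_1:{cons}:10.0",
                    "ambiguous": False,
                    "filtered": False,
                }
            )
    sites = pd.DataFrame(rows)

    # ---- phase 2: isoform traps and tranche failures ---------------------
    if n_isoform_traps > 0:
        candidates = sites.index[~sites["x_linked"]]
        trap_idx = rng.choice(candidates, size=min(n_isoform_traps, len(candidates)), replace=False)
        for idx in trap_idx:
            gene = sites.at[idx, "gene"]
            sites.loc[idx, ["intervar", "clinvar", "hgmd", "pvs1", "ambiguous"]] = [
                "LP",
                "absent",
                "absent",
                True,
                True,
            ]
            sites.at[idx, "consequences"] = f"TX_{gene}_1:intronic:10.0;TX_{gene}_2:stop_gain:1.0"

    sites["filter"] = "PASS"
    n_fail = int(round(nonpass_fraction * len(sites)))
    if n_fail:
        for idx in rng.choice(sites.index, size=n_fail, replace=False):
            token = TRANCHE_INDEL if len(sites.at[idx, "ref"]) != len(sites.at[idx, "alt"]) else TRANCHE_SNP
            sites.at[idx, "filter"] = token
            sites.at[idx, "filtered"] = True

    # ---- phase 3: multiallelic grouping (before genotype draws) ----------
    sites["multi_with_prev"] = False
    for i in range(1, len(sites)):
        if (
            sites.at[i, "gene"] == sites.at[i - 1, "gene"]
            and not sites.at[i - 1, "multi_with_prev"]
            and sites.at[i, "target_aaf"] + sites.at[i - 1, "target_aaf"] < 0.9
            and rng.random() < multiallelic_fraction
        ):
            sites.at[i, "multi_with_prev"] = True
            sites.at[i, "pos"] = sites.at[i - 1, "pos"]
            sites.at[i, "ref"] = sites.at[i - 1, "ref"]
            taken = {sites.at[i - 1, "alt"], sites.at[i - 1, "ref"]}
            if sites.at[i, "alt"] in taken:
                sites.at[i, "alt"] = next(b for b in _BASES if b not in taken)
            sites.at[i, "filter"] = sites.at[i - 1, "filter"]
            sites.at[i, "filtered"] = bool(sites.at[i - 1, "filtered"])

    groups: list[list[int]] = []
    for i in sites.index:
        if sites.at[i, "multi_with_prev"] and groups:
            groups[-1].append(i)
        else:
            groups.append([i])

    # ---- phase 4: HWE allele draws per record ----------------------------
    n_sites = len(sites)
    acs = np.zeros(n_sites, dtype=np.int64)
    ans = np.zeros(n_sites, dtype=np.int64)
    dosages = None if sites_only else np.zeros((n_sites, n_individuals), dtype=np.int16)
    for grp in groups:
        x_linked = bool(sites.at[grp[0], "x_linked"])
        an = (2 * n_individuals - n_male) if x_linked else 2 * n_individuals
        freqs = np.array([sites.at[i, "target_aaf"] for i in grp])
        if sites_only:
            counts = rng.multinomial(an, np.append(freqs, 1.0 - freqs.sum()))[: len(grp)]
            for i, c in zip(grp, counts):
                acs[i], ans[i] = int(c), an
            continue
        ploidy = np.where(sex == 1, 1, 2) if x_linked else np.full(n_individuals, 2)
        u = rng.random((n_individuals, 2))
        edges = np.concatenate([[0.0], np.cumsum(freqs)])
        for ai, i in enumerate(grp):
            carries = (u >= edges[ai]) & (u < edges[ai + 1])
            carries[:, 1] &= ploidy == 2
            d = carries.sum(axis=1).astype(np.int16)
            dosages[i] = d
            acs[i] = int(d.sum())
            ans[i] = int(ploidy.sum())
    sites["ac"] = acs
    sites["an"] = ans
    sites["true_aaf"] = np.where(ans > 0, acs / np.maximum(ans, 1), 0.0)

    # ---- phase 5: truth tiers and outputs --------------------------------
    tiers = []
    for row in sites.itertuples(index=False):
        intervar = "VUS" if row.ambiguous else row.intervar
        tiers.append(decision_table_tier(intervar, row.clinvar, row.hgmd, row.true_aaf, maf_threshold))
    sites["true_tier"] = tiers

    truth_cols = ["chrom", "pos", "ref", "alt", "gene", "true_tier", "true_aaf", "ambiguous", "filtered"]
    truth = SyntheticTruth(
        seed=seed,
        n_individuals=n_individuals,
        variants=sites[truth_cols].copy(),
        q_per_gene=_truth_q(sites),
    )

    vcf_path = annotation_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vcf_path = out_dir / "cohort.vcf"
        annotation_path = out_dir / "annotation.tsv"
        _write_vcf(vcf_path, sites, groups, dosages, sex, panel, sites_only)
        _write_annotation(annotation_path, sites)
        truth.to_json(out_dir / "truth.json")

    return SyntheticCohort(
        vcf_path=vcf_path,
        annotation_path=annotation_path,
        truth=truth,
        sites=sites,
        dosages=dosages,
        sex=sex,
    )


def _write_vcf(
    path: Path,
    sites: pd.DataFrame,
    groups: list[list[int]],
    dosages: np.ndarray | None,
    sex: np.ndarray,
    panel: Sequence[GenePanelEntry],
    sites_only: bool,
) -> None:
    """Write VCFv4.2 text; grouped rows become multiallelic records with
    per-allele AC/AF."""
    n_ind = len(sex)
    samples = [] if sites_only else [f"S{i:05d}" for i in range(n_ind)]
    lines = ["##fileformat=VCFv4.2"]
    for chrom in dict.fromkeys(e.chrom for e in panel):
        lines.append(f"##contig=<ID={chrom}>")
    lines += [
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total called alleles">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">',
        f'##FILTER=<ID={TRANCHE_SNP},Description="VQSR tranche">',
        f'##FILTER=<ID={TRANCHE_INDEL},Description="VQSR tranche">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        header += "\tFORMAT\t" + "\t".join(samples)
    lines.append(header)

    records = []
    for grp in groups:
        first = sites.loc[grp[0]]
        alts = [sites.at[i, "alt"] for i in grp]
        acs = [int(sites.at[i, "ac"]) for i in grp]
        an = int(first["an"])
        afs = [f"{a / an:.6g}" if an else "0" for a in acs]
        info = f"AC={','.join(map(str, acs))};AN={an};AF={','.join(afs)}"
        fields = [
            str(first["chrom"]),
            str(int(first["pos"])),
            ".",
            str(first["ref"]),
            ",".join(alts),
            ".",
            str(first["filter"]),
            info,
        ]
        if samples:
            ploidy = (np.where(sex == 1, 1, 2) if first["x_linked"] else np.full(n_ind, 2))
            alt_dosage = np.stack([dosages[i] for i in grp])  # (n_alts, n_ind)
            gts = []
            for ind in range(n_ind):
                alleles: list[str] = []
                for ai in range(len(grp)):
                    alleles += [str(ai + 1)] * int(alt_dosage[ai, ind])
                while len(alleles) < ploidy[ind]:
                    alleles.insert(0, "0")
                gts.append("/".join(alleles))
            fields += ["GT", "\t".join(gts)]
        records.append((fields[0], int(fields[1]), "\t".join(fields)))

    records.sort(key=lambda r: (r[0], r[1]))
    lines += [r[2] for r in records]
    path.write_text("\n".join(lines) + "\n")


def _write_annotation(path: Path, sites: pd.DataFrame) -> None:
    df = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "ref": sites["ref"],
            "alt": sites["alt"],
            "clinvar": sites["clinvar"],
            "intervar": sites["intervar"],
            "hgmd": sites["hgmd"],
            "acmg_criteria": np.where(sites["pvs1"], "PVS1,PM2", "PM2"),
            "consequences": sites["consequences"],
            "class_without_pvs1": "",
        }
    )
    df.to_csv(path, sep="\t", index=False)


def inject_platform_bias(
    n_variants: int = 200,
    platforms: Sequence[str] = ("HiSeq162PE", "HiSeq259PE", "NovaSeq150PE"),
    biased_fraction: float = 0.1,
    effect: float = 5.0,
    alleles_per_platform: int = 2000,
    aaf_sampler=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Platform allele-count table with a known subset of distorted variants.

    Unbiased variants share one allele frequency across platforms; biased ones
    have the frequency multiplied by ``effect`` (clipped below 1) on the first
    platform. Returns the long-format count table and truth flags (a flag is
    recorded even for ``effect=1.0``, where the distortion is null).
    """
    rng = np.random.default_rng(seed)
    if aaf_sampler is None:
        aafs = 10 ** (np.log10(1e-3) + rng.random(n_variants) * (np.log10(0.05) - np.log10(1e-3)))
    else:
        aafs = aaf_sampler(rng, n_variants)
    biased = rng.random(n_variants) < biased_fraction
    rows = []
    truth = {}
    for i in range(n_variants):
        key = f"v{i:04d}"
        truth[key] = bool(biased[i])
        for j, plat in enumerate(platforms):
            f = aafs[i]
            if biased[i] and j == 0:
                f = min(f * effect, 0.99)
            alt = int(rng.binomial(alleles_per_platform, f))
            rows.append(
                {
                    "key": key,
                    "platform": plat,
                    "alt_count": alt,
                    "ref_count": alleles_per_platform - alt,
                }
            )
    return pd.DataFrame(rows), truth


def make_isoform_trap(
    gene: str,
    major_weight: float,
    minor_weight: float,
    chrom: str = "chr1",
    pos: int = 1000,
    aaf: float = 0.001,
    an: int = 10000,
):
    """A variant whose LOF consequence sits only on the minor transcript.

    The major transcript reads intronic, so the PVS1-supported LP call should
    be demoted and flagged ambiguous downstream. Equal weights are refused: a
    tie makes both transcripts major and the construction is not a trap.
    """
    from .ingest import AnnotatedVariant, TranscriptConsequence
    from .panel import ClassLabel

    if not major_weight > minor_weight >= 0:
        raise ValueError(
            f"need major_weight > minor_weight >= 0, got {major_weight}, {minor_weight}"
        )
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref="C",
        alt="T",
        gene=gene,
        an=an,
        ac=int(round(aaf * an)),
        clinvar="absent",
        intervar=ClassLabel.LP,
        hgmd="absent",
        acmg_criteria=frozenset({"PVS1", "PM2"}),
        consequences=(
            TranscriptConsequence(f"TX_{gene}_major", "intronic", major_weight),
            TranscriptConsequence(f"TX_{gene}_minor", "stop_gain", minor_weight),
        ),
    )


_HI_PARAMS = {
    # category -> (pli beta a,b), (episcore beta a,b); GD most intolerant
    "GD": ((8.0, 2.0), (8.0, 2.0)),
    "HSA": ((1.0, 8.0), (2.0, 6.0)),
    "CHG": ((2.0, 2.0), (2.0, 6.0)),
}


def generate_hi_scores(
    panel: Sequence[GenePanelEntry] | None = None,
    seed: int = 0,
    missing_fraction: float = 0.0,
) -> pd.DataFrame:
    """Synthetic pLI/Episcore table shaped like published constraint scores.

    Category medians are ordered GD > CHG ≥ HSA for both scores, mirroring the
    intolerance pattern of gonadal-dysfunction genes. ``missing_fraction``
    blanks a random subset of cells.
    """
    panel = list(panel) if panel is not None else load_panel()
    rng = np.random.default_rng(seed)
    rows = []
    for e in panel:
        (pa, pb), (ea, eb) = _HI_PARAMS[e.category.value]
        rows.append(
            {
                "gene": e.gene_symbol,
                "pli": float(rng.beta(pa, pb)),
                "episcore": float(rng.beta(ea, eb)),
            }
        )
    df = pd.DataFrame(rows)
    if missing_fraction > 0:
        for col in ("pli", "episcore"):
            mask = rng.random(len(df)) < missing_fraction
            df.loc[mask, col] = np.nan
    return df
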