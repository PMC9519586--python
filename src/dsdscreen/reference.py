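"""Loaders for the published summary tables of the 8.3KJPN reference-panel
screen (8380 Japanese individuals, 32 recessive DSD/CHG genes).

These are the screen's printed results, packaged so that the derived
arithmetic — tier-set sizes, carrier denominators, biallelic-risk totals and
fold changes — can be re-derived and checked without access to the
access-controlled cohort data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

__all__ = [
    "reported_tier_counts",
    "reported_class_counts",
    "reported_biallelic_risk",
    "reported_summary",
]


def _data(name: str):
    return resources.files("dsdscreen.data") / name


def reported_tier_counts() -> pd.DataFrame:
    """Per-gene cumulative candidate-variant counts (columns set1..set4)."""
    with resources.as_file(_data("reported_tier_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#", index_col="gene")


def reported_class_counts() -> pd.Series:
    """Five-class interpretation counts over all panel variants."""
    with resources.as_file(_data("reported_class_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", index_col="class")
    return df["count"]


def reported_biallelic_risk() -> pd.DataFrame:
    """Category × tier biallelic-inactivation proportions (AR row = male
    hemizygote risk, excluded from autosomal totals)."""
    with resources.as_file(_data("reported_biallelic_risk.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#", index_col="category")


def reported_summary() -> dict:
    """Reported scalar quantities (cohort size, per-tier Q totals, AR male
    risk, CYP21A2 allele frequencies)."""
    with resources.as_file(_data("reported_summary.yaml")) as p:
        return yaml.safe_load(p.read_text())
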