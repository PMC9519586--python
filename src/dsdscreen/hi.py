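"""Haploinsufficiency-intolerance comparison across gene categories.

Two published gene-level scores are compared between the GD, HSA and CHG
categories:

* **pLI** — probability of being loss-of-function intolerant, estimated from
  the depletion of LOF variants in large exome aggregates; analysed on a
  log10 scale (genes with pLI = 0 are excluded from the log vector, never
  pseudo-counted).
* **Episcore** — a machine-learned haploinsufficiency prediction from
  epigenomic features.

Group comparisons use the pooled-variance (Student's) two-sample t test,
two-sided, with Welch available behind a flag; no multiple-testing correction
is applied across the three pairwise contrasts (raw p values are reported as
such). Box summaries use min/Q1/median/Q3/max with linear-interpolation
quartiles.
"""

from __future__ import annotations

import itertools
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import Category, GenePanelEntry

logger = logging.getLogger(__name__)

__all__ = ["read_scores", "group_scores", "two_sample_t", "box_stats", "pairwise_tests", "plot_scores"]


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read the score TSV (gene, pli, episcore); blank cells mean missing."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene", "pli", "episcore"):
        if col not in df.columns:
            raise ValueError(f"score TSV missing column {col!r}")
    return df


def group_scores(
    records: pd.DataFrame, panel: Sequence[GenePanelEntry]
) -> dict[str, dict[str, np.ndarray]]:
    """Per-category score vectors: {"log_pli" | "episcore" -> {GD/HSA/CHG -> values}}.

    Every record's gene must be in the panel (hard error otherwise). Missing
    scores are dropped with a logged count; pLI = 0 contributes to episcore
    but not to the log_pli vector.
    """
    cat_of = {e.gene_symbol: e.category.value for e in panel}
    unknown = sorted(set(records["gene"]) - set(cat_of))
    if unknown:
        raise ValueError(f"genes not in panel: {unknown}")
    out: dict[str, dict[str, list[float]]] = {
        "log_pli": {c.value: [] for c in Category},
        "episcore": {c.value: [] for c in Category},
    }
    n_missing = 0
    for row in records.itertuples(index=False):
        cat = cat_of[row.gene]
        pli = getattr(row, "pli", None)
        epi = getattr(row, "episcore", None)
        if pli is None or pd.isna(pli):
            n_missing += 1
        elif pli > 0:
            out["log_pli"][cat].append(math.log10(pli))
        if epi is None or pd.isna(epi):
            n_missing += 1
        else:
            out["episcore"][cat].append(float(epi))
    if n_missing:
        logger.info("dropped %d missing score value(s)", n_missing)
    return {
        score: {cat: np.asarray(vals, dtype=float) for cat, vals in groups.items()}
        for score, groups in out.items()
    }


def two_sample_t(x: Sequence[float], y: Sequence[float], welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t test (pooled variance unless ``welch``).

    Returns (t, p); degrees of freedom are |x|+|y|-2 for the pooled test.
    Fewer than two observations in either group is a hard error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def box_stats(v: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(min, Q1, median, Q3, max), quartiles by linear interpolation."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return float(v.min()), float(q25), float(q50), float(q75), float(v.max())


def pairwise_tests(groups: dict[str, np.ndarray], welch: bool = False) -> pd.DataFrame:
    """All pairwise category contrasts for one score (raw p, uncorrected)."""
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        t, p = two_sample_t(groups[a], groups[b], welch=welch)
        rows.append({"group_a": a, "group_b": b, "t": t, "p": p})
    return pd.DataFrame(rows)


def plot_scores(grouped: dict[str, dict[str, np.ndarray]], path: str | Path) -> None:
    """Side-by-side box-whisker plots (whiskers at min/max) for both scores."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [c.value for c in Category]
    fig, axes = plt.subplots(1, len(grouped), figsize=(4 * len(grouped), 4))
    if len(grouped) == 1:
        axes = [axes]
    for ax, (score, groups) in zip(axes, grouped.items()):
        data = [groups[c] for c in order]
        ax.boxplot(data, tick_labels=order, whis=(0, 100))
        ax.set_title(score)
        ax.set_xlabel("gene category")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
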