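#!/usr/bin/env python
"""Carrier and biallelic-risk estimates from the step-02 classification.

Summarizes per-gene cumulative pathogenic allele frequencies Q, the
Hardy-Weinberg carrier fractions 2(1-Q)Q, category-level biallelic risk
(Q² autosomal, Q/3 X-linked), and the genotype census (homozygotes,
unphased compound heterozygotes, multi-gene carriers).
"""

import json
from pathlib import Path

import pandas as pd

OUT = Path("scratch/pipeline")
RESULTS = Path("results")


def main() -> None:
    for name in ("per_gene_estimates.tsv", "category_summary.tsv", "carrier_summary.tsv"):
        (RESULTS / f"03_{name}").write_text((OUT / name).read_text())

    carrier = pd.read_csv(OUT / "carrier_summary.tsv", sep="\t")
    census = pd.read_csv(OUT / "census.tsv", sep="\t")
    manifest = json.loads((OUT / "run_manifest.json").read_text())

    print("Cohort-wide carrier fraction per tier (pooled 2(1-Q)Q form):")
    for r in carrier.itertuples(index=False):
        print(f"  {r.tier}: Q_total={r.q_total:.5f}  carrier={r.pooled:.5f} ({r.pooled_display})")
    kinds = census["kind"].value_counts().to_dict() if len(census) else {}
    print("Census:", kinds)
    (RESULTS / "03_census_summary.json").write_text(
        json.dumps({"census_kinds": kinds, "funnel": manifest["funnel"]}, indent=1)
    )


if __name__ == "__main__":
    main()
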