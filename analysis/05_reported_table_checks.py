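#!/usr/bin/env python
"""Re-derive the reference screen's printed summary arithmetic.

From the packaged published tables: cumulative set sizes (14/42/57/91 with 28
novel candidates and 8 candidate-free genes), the five-class partition total
(49,622), the "1 in N" conversions (CYP21A2 homozygote rate, AR male risk,
strictest-tier biallelic total), and the category-table consistency checks
(Set-2 total at 3 s.f., HSA fold change 2.37).
"""

from dsdscreen import reference
from dsdscreen.carriers import biallelic_risk, one_in_n
from dsdscreen.pipeline import format_one_in_n, sci3


def main() -> None:
    counts = reference.reported_tier_counts()
    sums = counts.sum()
    print(f"Class partition total: {reference.reported_class_counts().sum()}")
    print(f"Cumulative set sizes: {sums.tolist()} (novel = {sums.set2 - sums.set1})")
    print(f"Genes without candidates: {(counts.sum(axis=1) == 0).sum()}")

    s = reference.reported_summary()
    hom = biallelic_risk(s["cyp21a2_set4_maf"], "autosomal_recessive")
    print(f"CYP21A2 HGMD-DM allele Q={s['cyp21a2_set4_maf']}: homozygous {format_one_in_n(hom, thousands=True)}")
    ar = biallelic_risk(s["ar_q"], "x_linked_recessive")
    print(f"AR male risk: Q/3 = {ar:.6f} (1 in {one_in_n(ar)} male births)")

    bi = reference.reported_biallelic_risk().loc[["GD", "HSA", "CHG"]]
    print(f"Strictest-tier biallelic total: {format_one_in_n(bi['set1'].sum(), thousands=True)} births")
    print(f"Set-2 total at 3 s.f.: {sci3(bi['set2'].sum())}")
    print(f"HSA Set3/Set2 fold change: {bi.loc['HSA','set3']/bi.loc['HSA','set2']:.2f}")


if __name__ == "__main__":
    main()
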