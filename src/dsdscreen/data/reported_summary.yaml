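# Scalar quantities reported for the 8.3KJPN reference panel screen,
# used as inputs when re-deriving carrier and biallelic-risk figures.
cohort_size: 8380
# Cumulative pathogenic allele frequency (Q) totals over all genes per tier,
# after removing the three isoform-ambiguous variants.
total_q:
  set1: 0.00322
  set2: 0.00668
  set3: 0.01248
  set4: 0.02997
# AR (X-linked): cumulative frequency of the three HGMD-DM alleles; the
# hemizygous-male risk convention reports Q/3 (= 0.000436).
ar_q: 0.001308
# CYP21A2 candidate alleles.
cyp21a2_set3_maf: 0.00256   # c.293-13C>G, ClinVar P/LP
cyp21a2_set4_maf: 0.00584   # p.Ala392Thr, HGMD DM only
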