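# Estimated biallelic-inactivation proportions per gene category and cumulative
# evidence tier, as reported for the 8.3KJPN reference panel screen.
# AR is hemizygous-male risk (Q/3) and is excluded from the autosomal total.
category	set1	set2	set3	set4
GD	0	1.86e-7	1.86e-7	1.86e-7
HSA	4.71e-6	8.13e-6	1.93e-5	1.46e-4
AR	0	0	0	4.37e-4
CHG	1.44e-8	1.72e-7	1.97e-7	2.00e-7
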