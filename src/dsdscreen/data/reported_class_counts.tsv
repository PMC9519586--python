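# ACMG five-class counts (automated InterVar-style interpretation) reported for
# the 49,622 variants of the 32-gene panel in the 8.3KJPN reference panel.
class	count
P	13
LP	29
VUS	43856
LB	445
B	5279
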