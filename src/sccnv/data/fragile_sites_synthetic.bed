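# Synthetic fragile-site catalogue for tests and demos.
# NOT the HumanCFS database: intervals are invented stand-ins placed near
# breakpoints of the packaged per-cell CNV table. BED4, 0-based half-open.
chr1	28000000	33000000	FRA1D
chr1	92000000	96000000	FRA1M
chr1	148000000	152500000	FRA1F
chr2	96000000	99500000	FRA2A
chr2	133000000	136500000	FRA2S-2F
chr3	59500000	61500000	FRA3B
chr3	148000000	151000000	FRA3D
chr4	53000000	56000000	FRA4b
chr5	24500000	27500000	FRA5E
chr7	67500000	70500000	FRA7J
chr8	101500000	104500000	FRA8A
chr10	102500000	105500000	FRA10A
chr11	66500000	69500000	FRA11EH
chr12	46500000	49500000	FRA12A
chr13	57500000	60000000	FRA13b
chr16	27500000	30500000	FRA6E
chr16	79500000	82500000	FRA16D
chr17	57000000	60000000	FRA17B
chr18	53000000	56000000	FRA18B
chr20	10000000	13000000	FRA20B
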