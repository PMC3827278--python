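taxon	n_before_filters	n_after_filters
V. rotundifolia	71	68
V. acerifolia	18	15
V. aestivalis	55	42
V. cinerea	98	70
V. doaniana	5
V. girdiana	4	4
V. labrusca	36	23
V. monticola	5	4
V. mustangensis	7	5
V. palmata	13	9
V. riparia	113	73
V. rupestris	48	36
V. vulpina	23	15
V. x champinii	15	12
V. amurensis	22	13
V. coignetiae	6	3
V. piasezkii	9	9
V. sylvestris	59	59
V. vinifera	570	570
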