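# Structural category annotation of V-domain framework positions
# (1 solvent-exposed, 2 hydrophobic core, 3 Va-Vb interface, 4 V-C interface).
# Static, user-replaceable annotation; 3D modeling itself is out of scope.
chain	imgt_position	category_code
alpha	3	1
alpha	5	1
alpha	19	2
alpha	20	1
alpha	24	2
alpha	39	3
alpha	50	3
alpha	55	3
alpha	86	2
alpha	90	4
alpha	96	4
beta	6	2
beta	9	4
beta	10	4
beta	22	1
beta	43	3
beta	86	2
beta	90	4
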