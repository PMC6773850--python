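# Curated 14-residue candidate set: framework positions whose dominant-library
# residue identity distinguishes dominantly from weakly expressed TCRs.
# Categories: 1 solvent-exposed, 2 hydrophobic core, 3 Va-Vb interface,
# 4 V-C interface.  Identities not individually documented are curated
# stand-ins (synthetic transcription).
chain	imgt_position	dominant_aa	weak_aa	category_code	evidence
alpha	5	T	S	1	curated
alpha	19	V	S	2	curated
alpha	20	T	S	1	curated
alpha	24	T	A	2	curated
alpha	39	L	F	3	curated
alpha	50	M	T	3	curated
alpha	55	R	D	3	curated
alpha	86	S	H	2	curated
alpha	96	L	P	4	curated
beta	6	L	V	2	curated
beta	9	R	S	4	curated
beta	10	Y	N	4	curated
beta	43	Q	R	3	curated
beta	86	V	A	2	curated
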