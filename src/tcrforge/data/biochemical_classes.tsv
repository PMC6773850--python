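# Biochemical residue classes used for equivalence expansion of designed
# substitutions (Taylor-style grouping; user-editable).  A residue's primary
# class is the first class listed that contains it.
class	members
hydrophobic	LIVMF
basic	RKH
aromatic	FWYH
acidic	DE
polar	STNQY
small	AGSCP
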