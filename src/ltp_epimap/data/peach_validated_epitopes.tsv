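# The three experimentally mapped IgE-binding epitopes of peach nsLTP (Pru p 3),
# the reference standard of the LTP allergen family. Epitope 2 is quoted in the
# source literature with a 15-position range but a 16-residue string; the string
# is treated as authoritative and the discrepancy is recorded, not resolved.
parent_id	epitope_index	start	end	sequence	kind	note
peach	1	11	25	APCIPYVRGGGAVPP	validated
peach	2	31	45	IRNVNNLARTTTPDRQ	validated	range 31-45 spans 15 positions but the reported string has 16 residues; string kept as authoritative
peach	3	71	80	GKCGVSIPYK	validated
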