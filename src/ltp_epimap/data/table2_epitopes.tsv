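# Consensus linear/conformational IgE-binding epitope regions predicted for the
# five legume nsLTP queries (>=5-of-8 predictor consensus); shipped as a fixture
# for downstream shared-motif and PD analysis. kind: linear = exclusively linear;
# overlapping_linear_conformational = overlapping linear + conformational region.
parent_id	epitope_index	start	end	sequence	kind	note
chickpea	1	35	50	APCLGYLQGGPGPSAQ	linear
chickpea	2	56	70	RNLNSAAVTTPDRQA	overlapping_linear_conformational
chickpea	3	82	112	ISRLNANNAAALPGKCVVNIPYKISTSTNCA	overlapping_linear_conformational
mung_bean	1	26	50	ITCGQVASSLAPCISYLQKGGVPSA	overlapping_linear_conformational
mung_bean	2	59	70	LNSAASTTADRK	overlapping_linear_conformational
mung_bean	3	75	110	CLKNLAGPKSGINEGNAASLPGKCKVNVPYKISTFT	overlapping_linear_conformational
cowpea	1	29	35	AEAVTCN	linear
cowpea	2	37	50	TELSSCVPAITGGS	overlapping_linear_conformational
cowpea	3	53	65	SSTCCSKLKVQEP	overlapping_linear_conformational
cowpea	4	72	81	KNPSLKQYVN	overlapping_linear_conformational
cowpea	5	93	99	GVTYPNC	overlapping_linear_conformational
pigeon_pea	1	25	39	ASDIPATCNGDEPVL	linear
pigeon_pea	2	47	55	VNKVPNPSS	overlapping_linear_conformational
pigeon_pea	3	69	79	MGDNTGQGIRD	overlapping_linear_conformational
pigeon_pea	4	124	131	LSNQEKNY	overlapping_linear_conformational
soybean	1	3	10	MGGGCKCL	overlapping_linear_conformational
soybean	2	21	33	RSLAEAQSGSSTT	overlapping_linear_conformational
soybean	3	46	51	NGTTTP	overlapping_linear_conformational
soybean	4	59	66	LKQTVENQ	overlapping_linear_conformational
soybean	5	108	120	NGSAPAPGSGPPP	linear
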