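protein_name	accession	figure	indel_size_aa	indel_kind	location	specificity	source_table	flags
junctional protein associated with coronary artery disease	BAD90447	Fig 2A	1	Ins	792-822	Glires	1
adenylyl cyclase-associated protein 2	EDL41025	Fig 2B	1	Del	280-313	Glires and Scandentia	1
activity-dependent neuroprotector homeobox protein 2	XP_036017036	Fig 3A	28	Ins	696-747	Rodentia	1	size_discrepancy_body_text_says_29
optineurin	NP_001343416	Fig 3B	3	Del	153-178	Lagomorpha	1
U3 small nucleolar RNA-associated protein 6 homolog	74146777	Appendix	1	Ins	192-227	Lagomorpha	1
ankyrin repeat and KH domain-containing protein 1	NP_780584	Appendix	1	Ins	1893-1927	Lagomorpha	1
prickle-like protein 1	NP_001028389	Appendix	3	Del	553-586	Lagomorpha	1
vasopressin V1a receptor	74146437	Fig 4A	2	Ins	176-215	Myomorpha	2
nck-associated protein 5-like isoform X1	XP_006521185	Appendix	1	Del	584-619	Myomorpha	2
ATP-dependent DNA helicase DDX11 isoform 1	NP_001335221	Appendix	3	Ins	481-514	Myomorpha	2
F-actin-uncapping protein LRRC16A	BAC31591	Appendix	1	Del	1150-1174	Myomorpha	2
zinc finger E-box-binding homeobox 1	XP_030106271	Fig 4B	1	Del	737-775	Castorimorpha	2
cAMP-responsive element modulator	XP_030106165	Appendix	1	Del	150-186	Castorimorpha	2
leukocyte elastase inhibitor A	EDL32356	Fig 5A	2	Del	242-277	Hystricomorpha	2
sterol regulatory element-binding protein cleavage-activating protein	AAH70437	Appendix	1	Del	1040-1077	Hystricomorpha	2
early endosome antigen 1 isoform X1	XP_006513587	Appendix	1	Del	58-91	Hystricomorpha	2
tudor domain-containing protein 1	NP_001002238	Appendix	1	Del	42-74	Hystricomorpha	2
tudor domain-containing protein 1	AAI29955	Appendix	6	Del	669-703	Hystricomorpha	2
autophagy-related protein 9A isoform a	XP_011236992	Appendix	2	Ins	659-687	Hystricomorpha	2
probable small intestine urate exporter	XP_006516763	Appendix	2	Ins	429-469	Hystricomorpha	2
ryanodine receptor 2	NP_076357	Fig 5B	1	Del	1326-28	Sciuromorpha	2	abbreviated_range_printed_1326-28
A disintegrin and metallo-proteinase with thrombospondin motifs 13 isoform 1 preproprotein	NP_001001322	Appendix	2	Del	1072-1109	Sciuromorpha	2
telomerase-binding protein EST1A	EDL12790	Appendix	1	Del	472-503	Sciuromorpha	2
oxysterol-binding protein-related protein 8 isoform b	XP_006513700	Appendix	1	Ins	816-844	Sciuromorpha	2
rab-3A-interacting protein isoform 2	NP_001003950	Appendix	1	Del	36-67	Sciuromorpha	2
dual specificity protein phosphatase CDC14B	XP_036013890	Appendix	2	Ins	335-370	Sciuromorpha	2
zinc finger protein 385A	NP_038894	Appendix	1	Del	7-44	Sciuromorpha	2
rho family-interacting cell polarization regulator 2	BAE37527	Appendix	1	Ins	336-371	Sciuromorpha	2
rho family-interacting cell polarization regulator 2	XP_006516650	Appendix	5	Del	587-625	Sciuromorpha	2
ATP-dependent DNA helicase DDX11 isoform 1	XP_006524473	Fig 6	1	Del	262-289	Myomorpha and Castorimorpha	2	exception_lacking_in_Jaculus_jaculus
voltage-dependent L-type calcium channel subunit beta-2	XP_006497377	Appendix	1	Ins	375-401	Myomorpha and Castorimorpha	2	exceptions_18_of_19_Myomorpha_and_Dipodomys_ordii
cyclin-dependent kinase-like 2	74177560	Fig 7A	2	Ins	232-263	Muridae and Cricetidae	3
nck-associated protein 5-like	NP_001001884	Appendix	1	Del	782-817	Muridae and Cricetidae	3
lysosomal acid glucosylceramidase	568921788	Appendix	1	Del	276-308	Muridae and Cricetidae	3
cAMP-responsive element modulator	NP_001104322	Appendix	1	Del	61-91	Muridae and Cricetidae	3
cyclin-dependent kinase 13	XP_006516830	Appendix	1	Del	549-582	Muridae and Cricetidae	3
voltage-dependent L-type calcium channel subunit beta-2	XP_036013681	Appendix	1	Del	444-474	Muridae and Cricetidae	3
CREB-regulated transcription coactivator 1	XP_006509763	Fig 7B	4	Del	270-297	Muroidea	3
striatin-interacting proteins 2	148681817	Appendix	1	Ins	86-119	Muroidea	3
disco-interacting protein 2 homolog C	BAC29340	Appendix	4	Ins	953-988	Muroidea	3
zinc finger protein 40	XP_006516902	Appendix	1	Del	2511-2535	Muroidea	3
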