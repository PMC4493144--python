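Species	Strait of Sicily	Capo Passero	Levantine Sea
Auxis rochei	53	0	21
Euthynnus alletteratus	2	0	12
Scomber japonicus	1	0	0
Thunnus alalunga	11	0	0
Thunnus thynnus	21	58	0
Non-scombrid larvae	4	0	5
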