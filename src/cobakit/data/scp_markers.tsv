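marker_id	gene_symbol	profile_accessions	module	branch	required	weight
cobA	cobA	K00589	precursor	shared	true	1.0
hemC	hemC	K01749	precursor	shared	false	1.0
hemD	hemD	K01719	precursor	shared	false	1.0
cobG	cobG	K02229	ring	aerobic	true	1.0
cobJ	cobJ	K02230	ring	aerobic	true	1.0
cobM	cobM	K05936	ring	aerobic	true	1.0
cobF	cobF	K05934	ring	aerobic	true	1.0
cobK	cobK	K05895	ring	aerobic	true	1.0
cobL	cobL	K00595	ring	aerobic	true	1.0
cobH	cobH	K06042	ring	aerobic	true	1.0
cbiL	cbiL	TIGR01467	ring	anaerobic	true	1.0
cbiH	cbiH	TIGR01466	ring	anaerobic	true	1.0
cbiF	cbiF	TIGR01465	ring	anaerobic	true	1.0
cbiD	cbiD	TIGR00379	ring	anaerobic	true	1.0
cbiG	cbiG	TIGR01650	ring	anaerobic	true	1.0
cbiC	cbiC	TIGR01651	ring	anaerobic	true	1.0
cbiA	cbiA	TIGR01653	ring	anaerobic	true	1.0
cobN	cobN	TIGR02257	chelation	aerobic	true	1.0
cobS_chl	cobS	TIGR02459	chelation	aerobic	false	1.0
cobT_chl	cobT	TIGR02460	chelation	aerobic	false	1.0
cbiK	cbiK	TIGR02150	chelation	anaerobic	true	1.0
cbiX	cbiX	TIGR02287	chelation	anaerobic	false	1.0
cobO	cobO	K00798	adenosylation	shared	true	1.0
pduO	pduO	K19221	adenosylation	shared	false	1.0
cobQ	cobQ	K02232	loop	shared	true	1.0
cobD	cobD	K02227	loop	shared	true	1.0
cobU	cobU	K02231	loop	shared	true	1.0
cobS_loop	cobS	K02233	loop	shared	true	1.0
cobT_loop	cobT	K00768	loop	shared	true	1.0
btuB	btuB	K16092	salvage	shared	false	1.0
btuF	btuF	K06858	salvage	shared	false	1.0
btuC	btuC	K06073	salvage	shared	false	1.0
btuD	btuD	K06074	salvage	shared	false	1.0
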