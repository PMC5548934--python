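id	cdna	protein	class	protein_pos	exon
V01	c.480+1G>A	.	splice_donor	.	5
V02	c.598-2A>G	.	splice_acceptor	.	8
V03	c.298C>T	p.Arg100Ter	nonsense	100	4
V04	c.715C>T	p.Arg239Ter	nonsense	239	8
V05	c.862C>T	p.Gln288Ter	nonsense	288	8
V06	c.2077G>T	p.Glu693Ter	nonsense	693	11
V07	c.148del	p.Leu50fs	frameshift	50	2
V08	c.418del	p.Ser140fs	frameshift	140	5
V09	c.658del	p.Lys220fs	frameshift	220	8
V10	c.1198del	p.Thr400fs	frameshift	400	9
V11	c.1738del	p.Ala580fs	frameshift	580	10
V12	c.1079A>C	p.Gln360Pro	missense	360	9
V13	c.1120G>A	p.Glu374Lys	missense	374	9
V14	c.1165C>T	p.Arg389Cys	missense	389	9
V15	c.1190T>G	p.Leu397Arg	missense	397	9
V16	c.1229G>A	p.Gly410Asp	missense	410	9
V17	c.1273C>G	p.Arg425Gly	missense	425	9
V18	c.1543G>A	p.Gly515Ser	missense	515	10
V19	c.1696C>A	p.Gln566Lys	missense	566	10
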