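label	species
llama	Lama glama
lama glama	Lama glama
llama glama	Lama glama
lama	Lama glama
l. glama	Lama glama
alpaca	Vicugna pacos
vicugna pacos	Vicugna pacos
lama pacos	Vicugna pacos
v. pacos	Vicugna pacos
dromedary	Camelus dromedarius
dromedary camel	Camelus dromedarius
camelus dromedarius	Camelus dromedarius
arabian camel	Camelus dromedarius
c. dromedarius	Camelus dromedarius
bactrian	Camelus bactrianus
bactrian camel	Camelus bactrianus
camelus bactrianus	Camelus bactrianus
c. bactrianus	Camelus bactrianus
camel	AMBIGUOUS
camelid	AMBIGUOUS
camelidae	AMBIGUOUS
mixed library	AMBIGUOUS
mixed	AMBIGUOUS
unknown	AMBIGUOUS
synthetic	AMBIGUOUS
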