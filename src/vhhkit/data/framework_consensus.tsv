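species	FR1	FR2	FR3	FR4
Lama glama	QVQLVESGGGLVQAGGSLRLSCAAS	WFRQAPGKEREFVATIS	YYADSVKGRFTISRDNAKNTVYLQMNSLKPEDTACAVY	WGQGTQVTVSS
Vicugna pacos	QVQLVESGGGLVQPGGSLRLSCAAS	WFRQAPGKEREFVAAIS	YYADSVKGRFTISRDNAKNTVYLQMNSLKPEDTACAVY	WGQGTQVTVSS
Camelus dromedarius	QVQLVESGGGSVQAGGSLRLSCAAS	WFRQAPGKEREGVATIS	YYADSVKGRFTISQDNAKNTVYLQMNSLKPEDTACAVY	WGQGTQVTVSS
Camelus bactrianus	QVQLVESGGGSVQAGGSLRLSCAAS	WFRQAPGKEREGVATIS	YYADSVKGRFTISQDNAKNTVYLQMNSLKPEDTACAVY	WGQGTQVTVSS
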