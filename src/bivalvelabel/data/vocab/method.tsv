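# Production methods admissible on live bivalve labels.
aquaculture	Aquicultura	Aquacultura	Produzido em aquicultura
wild	Pesca extrativa	Capturado em meio selvagem	Apanha
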