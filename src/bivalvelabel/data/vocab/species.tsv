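# Bivalve species found on Portuguese retail labels.
# canonical<TAB>Portuguese common name<TAB>Latin binomial
pharus_legumen	Longueirão	Pharus legumen
ensis_spp	Lingueirão	Ensis spp
donax_spp	Conquilha	Donax spp
spisula_solida	Amêijoa-branca	Spisula solida
ruditapes_philippinarum	Amêijoa-japonesa	Ruditapes philippinarum
ruditapes_decussata	Amêijoa-boa	Ruditapes decussata
cerastoderma_edule	Berbigão	Cerastoderma edule
crassostrea_spp	Ostra	Crassostrea spp
mytilus_spp	Mexilhão	Mytilus spp
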