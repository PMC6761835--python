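# Countries of production seen in the Portuguese retail circuit.
portugal	Portugal
spain	Espanha	Spain	España
netherlands	Holanda	Países Baixos	Netherlands
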