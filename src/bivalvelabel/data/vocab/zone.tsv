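# Placeholder classified production-area codes (Portuguese coast + Galician
# rias style).  SYNTHETIC: not an authoritative registry — real deployments
# must supply the current official zone list.
L1	L1	Zona L1
L2	L2	Zona L2
L3	L3	Zona L3
L4	L4	Zona L4
L5A	L5a	Zona L5a
L6	L6	Zona L6
L7C	L7c	Zona L7c
RIAV1	RIAV1	Ria de Aveiro 1
RIAV2	RIAV2	Ria de Aveiro 2
ETJ1	ETJ1	Estuário do Tejo 1
ESD2	ESD2	Estuário do Sado 2
RIAF1	RIAF1	Ria Formosa 1
GAL01	GAL 01	Ria de Vigo
GAL02	GAL 02	Ria de Pontevedra
GAL03	GAL 03	Ria de Arousa
GAL04	GAL 04	Ria de Muros
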