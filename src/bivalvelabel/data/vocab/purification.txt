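# Keywords indicating the product passed through a purification (depuration)
# centre.  Matched fuzzily at a strict threshold to avoid false positives.
depurado
depuração
centro de depuração
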