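symbol	cell_type
Csf1r	macrophage
CSF1R	macrophage
Cd36	microglia
CD36	microglia
Calb1	neuron
CALB1	neuron
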