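>tata_tatawawa default plant TATA-box matrix (TATAWAWA consensus family)
A [ 0 4 0 4 2 4 2 4 ]
C [ 0 0 0 0 0 0 0 0 ]
G [ 0 0 0 0 0 0 0 0 ]
T [ 4 0 4 0 2 0 2 0 ]
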