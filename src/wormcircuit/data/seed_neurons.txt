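# 11 learning-correlated seed neurons (name<TAB>class)
ADF	sensory
ADL	sensory
AFD	sensory
ASH	sensory
ASI	sensory
ASJ	sensory
ASK	sensory
AWA	sensory
AWC	sensory
PVN	inter
CAN	motor
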