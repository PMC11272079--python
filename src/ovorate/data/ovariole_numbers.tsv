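species	ovariole_number
Dsim	33.9
Dsec	17.0
Dmel	39.2
Dyak	25.8
Dere	27.0
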