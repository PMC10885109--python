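>IGKJ1 synthetic stand-in J-region (Chothia 96-107)
WTFGGGTKLEIK
>IGLJ1 synthetic stand-in J-region (lambda)
WVFGGGTKLTVL
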