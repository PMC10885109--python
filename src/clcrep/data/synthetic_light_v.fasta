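>IGKV10-96 synthetic stand-in V-region (FR1 through Chothia 95)
DIQMTQSPSSLSASVGDRVTITCRASQGISNYLAWYQQKPGKAPKLLIYAASTLQSGVPSRFSGSGSGTDFTLTISSLQPEDFATYYCQQYNSYP
>IGKV14-111 synthetic stand-in V-region (FR1 through Chothia 95)
DIVMTQSPASLAVSLGQRATISCSASSSVSYMYAWYQQKPGKAPKLLIYDTSKLASGVPSRFSGSGSGTDFTLTISSLQPEDFATYYCQQWSSNP
>IGLV1 synthetic stand-in V-region (lambda)
QAVVTQESALTTSPGETVTLTCRSSTGAVTTSNYANWVQEKPDHLFTGLIGGTNNRAPGVPARFSGSLIGDKAALTITGAQTEDEAIYFCALWYSNH
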