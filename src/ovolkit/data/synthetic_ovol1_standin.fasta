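>OVOL1_HUMAN_SYNTHETIC synthetic stand-in, published motif coordinates
QSPGLAETKRVNDMIWQSPGLAETKRVNDMIWQSPGLAETKRVNDMIWQSPGLAETKRVN
DMIWQSPGLAETKRVNDMIWQSPGLAETKRVNDMIWQSPGLAETKRVNDMIWQSPGLCSP
CGLAFETKRVNDSHPGLAEHDMIWQCSPCGLAFETKRVNDSHPGLAEHKRVNDCSPGCLA
EFTKRVNDSPHGLAETHAETKRVNDMIWQSPGCSPGCLAEFTKRVNDSPHGLAETHDMIW
QSPGLAETKRVNDMIWQSPGLAETKRV
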