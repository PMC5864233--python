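>eBAC31A08 green-absorbing proteorhodopsin (uncultured gammaproteobacterium, Monterey Bay BAC clone 31A08)
MKLLLILGSVIALPTFAAGGGDLDASDYTGVSFWLVTAALLASTVFFFVERDRVSAKWKT
SLTVSGLVTGIAFWHYMYMRGVWIETGDSPTVFRYIDWLLTVPLLICEFYLILAAATNVA
GSLFKKLLVGSLVMLVFGYMGEAGIMAAWPAFIIGCLAWVYMIYELWAGEGKSACNTASP
AVQSAYNTMMYIIIFGWAIYPVGYFTGYLMGDGGSALNLNLIYNLADFVNKILFGLIIWN
VAVKESSNA
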