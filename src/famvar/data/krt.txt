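# 37 human epithelial/hair keratin coding genes. The cytokeratin control
# family is anchored on a count of 37 only; edit this file to swap symbols.
#family=KRT
KRT1
KRT2
KRT3
KRT4
KRT5
KRT6A
KRT6B
KRT6C
KRT7
KRT8
KRT9
KRT10
KRT12
KRT13
KRT14
KRT15
KRT16
KRT17
KRT18
KRT19
KRT20
KRT23
KRT24
KRT25
KRT26
KRT27
KRT28
KRT31
KRT32
KRT33A
KRT33B
KRT34
KRT35
KRT36
KRT37
KRT38
KRT40
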