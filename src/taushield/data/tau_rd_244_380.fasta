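>tau_rd|2N4R_244-380|repeat domain of human tau (0N4R-style core), absolute 2N4R numbering starts at 244
QTAPVPMPDLKNVKSKIGSTENLKHQPGGGKVQIINKKLDLSNVQSKCGSKDNIKHVPGG
GSVQIVYKPVDLSKVTSKCGSLGNIHHKPGGGQVEVKSEKLDFKDRVQSKIGSLDNITHV
PGGGNKKIETHKLTFRE
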