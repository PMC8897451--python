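>TOY0001.1 Sp1
A [  1  0  0  0  0  1  0  0  0 ]
C [  0  0  0  0 18  0  0  0  1 ]
G [ 17 18 18 18  0 17 18 18 17 ]
T [  0  0  0  0  0  0  0  0  1 ]
>TOY0002.1 C/EBP
A [  0  0  0  1  0  1 18 17 ]
C [  0  0  0  0 18  0  0  1 ]
G [  1  0 18  0  0 17  0  0 ]
T [ 17 18  0 17  0  0  0  0 ]
>TOY0003.1 GATA-1
A [ 17  0 18  0 18 17 ]
C [  0  0  0  0  0  1 ]
G [  1 18  0  0  0  0 ]
T [  0  0  0 18  0  0 ]
>TOY0004.1 N-Myc
A [  0  1  0  0  0  1 ]
C [ 18  0 17  0  0  0 ]
G [  0  0  0 18  0 17 ]
T [  0 17  1  0 18  0 ]
>TOY0005.1 TATA
A [  0 17  0 18 18  1 ]
C [  1  0  0  0  0  0 ]
G [  0  0  0  0  0  1 ]
T [ 17  1 18  0  0 16 ]
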