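>stat_like stat_like
A  [  0  0  0  0  0  0  0 12 12 ]
C  [  0  0 12 12 12  0  0  0  0 ]
G  [  0  0  0  0  0 12 12  0  0 ]
T  [ 12 12  0  0  0  0  0  0  0 ]
>nfkb_like nfkb_like
A  [  0  0  0 12  0  0  0  0  0  0 ]
C  [  0  0  0  0 12  0  0  0 12 12 ]
G  [ 12 12 12  0  0  0  0  0  0  0 ]
T  [  0  0  0  0  0 12 12 12  0  0 ]
>sp1_like sp1_like
A  [  0  0  0  0  0  0  0  0  0 ]
C  [  0  0  0  0 12  0  0  0  0 ]
G  [ 12 12 12 12  0 12 12 12 12 ]
T  [  0  0  0  0  0  0  0  0  0 ]
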