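# Synthetic toy TF-binding profiles in JASPAR PFM text format.
# These are stand-ins constructed for this package's tests and simulations;
# they are NOT profiles from the JASPAR database, only named after the
# transcription-factor families they caricature.
>TOY0001.1 ETS1
A [  2  94   2   2  94  94   2   2 ]
C [ 94   2   2   2   2   2   2   2 ]
G [  2   2  94  94   2   2  94   2 ]
T [  2   2   2   2   2   2   2  94 ]
>TOY0002.1 FOXD2
A [  2  2  94  94  94   2  94  94 ]
C [  2  2   2   2   2  94   2   2 ]
G [ 94  2   2   2   2   2   2   2 ]
T [  2 94   2   2   2   2   2   2 ]
>TOY0003.1 HOXB2
A [  2   2  94   2   2   2  94   2 ]
C [  2   2   2   2   2   2   2   2 ]
G [  2  94   2   2   2   2   2   2 ]
T [ 94   2   2  94  94  94   2  94 ]
>TOY0004.1 SOX10
A [ 94  94   2  94  94   2   2   2 ]
C [  2   2  94   2   2   2   2   2 ]
G [  2   2   2   2   2   2  94  94 ]
T [  2   2   2   2   2  94   2   2 ]
>TOY0005.1 YY1
A [  2   2   2   2  94   2   2   2 ]
C [ 94  94  94  94   2   2   2   2 ]
G [  2   2   2   2   2   2   2  94 ]
T [  2   2   2   2   2  94  94   2 ]
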