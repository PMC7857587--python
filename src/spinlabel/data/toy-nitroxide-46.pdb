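ATOM      1  N  RTM X   1      -1.458   0.000   0.000  1.00  0.00           N
ATOM      2  CA RTM X   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C  RTM X   1       0.551   1.422   0.000  1.00  0.00           C
ATOM      4  C1 RTM X   1      -0.161  -1.610   3.021  1.00  0.00           C
ATOM      5  N1 RTM X   1       0.274  -3.281   6.041  1.00  0.00           N
ATOM      6  O1 RTM X   1      -0.920  -3.161   6.041  1.00  0.00           O
END
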