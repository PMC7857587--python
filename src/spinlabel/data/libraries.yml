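toy-nitroxide-46:
  weights: toy-nitroxide-46_weights.txt
  topology: toy-nitroxide-46.pdb
  trajectory: toy-nitroxide-46_conformers.pdb
  triad:
    N: N
    CA: CA
    C: C
  nitroxide:
    N: N1
    O: O1
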