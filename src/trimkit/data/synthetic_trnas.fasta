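>tRNA-Leu-synthetic synthetic stand-in tRNA (not a database sequence)
GCCGAAGTGGCGAAATCGGTAGACGCAGTTGATTCAAAATCAACCGTAGAAATACGTGCCGGTTCGAATCCCCA
>tRNA-Met-synthetic synthetic stand-in tRNA (not a database sequence)
AGCAGAGTGGCGCAGCGGAAGCGTGCTGGGCCCATAACCCAGAGGTCGATGGATCGAAACCATCCTCTGCTACCA
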