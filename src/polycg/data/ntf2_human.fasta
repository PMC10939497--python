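>NTF2_HUMAN nuclear transport factor 2, monomer sequence (UniProt P61970)
MGDKPIWEQIGSSFIQHYYQLFDNDRTQLGAIYIDASCLTWEGQQFQGKAAIVEKLSSLP
FQKIQHSITAQDHQPTPDSCIISMVVGQLKADEDPIMGFHQMFLLKNINDAWVCTNDMFR
LALHNFG
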