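>synthetic_86nt_seed1_5p_24nt
AAAATTCCGGAGGAGTAATTAACG
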