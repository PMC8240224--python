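>DISC1_SYNTH synthetic DISC1-like stand-in; reported N-terminal-domain peptides placed at published coordinates (MPGGGPQ... 1-35, ARQCGLDSR 83-91)
MPGGGPQGAPAAAGGGGVSHRAGSRDCLPPAACFRAGSEELTALQNELVGAVSDLLHTES
PAQDLGVQTDALLEQLSQMEKKARQCGLDSRLEAELASAVSELQHAESGLNPDAKTWLAG
SPEGHQLAR
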