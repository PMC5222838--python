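# The 14 semiotic structures used in the listening experiment.
AABB-AAAA
AABB-AABB
AABB-AACC
AABB-BBAA
AABB-CCAA
AABB-CCAB
AABB-CCDE
ABCD-ABCD
ABCD-AECF
ABCD-BCDB
ABCD-CECF
ABCD-DABD
ABCD-EFAB
ABCD-EFGH
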