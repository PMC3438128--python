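"""Small worked-example inputs.

``GRAUX_OLIGO`` is the 62-nt synthetic AtGH3.3-derived promoter fragment
(the "GRAUX module": one G-box-related element followed by two auxin
response elements within ~30 bp) used as a hand-checkable scanning
example: under auto-antisense scanning it contains exactly one GRE
(BACGTV, as TACGTG) and two AUX2 (TGTCYS) occurrences, hence two
GRE→AUX2 module instances and no AUX2→GRE instance.
"""

GRAUX_OLIGO = (
    "AAAATTCACTAGTCAAAGATTACGTGACCGCGTCCCTCTTGTCCCCTGTCTCGGTCTAACGT"
)
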