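# Duplex ddPCR panel for Atlantic salmon / rainbow trout authentication.
# Both assays target the single-copy nuclear myoglobin (MB) gene.
assays:
  - species_label: atlantic_salmon
    gene: myoglobin
    accession: NM_001140642
    fwd_primer: GAGAGGTCACAGGGATAGGA
    rev_primer: CAAACCAGCACTTAGAATTTAC
    probe: AACTGGAAACTTACATTTGAAGCAG
    reporter_dye: HEX
    expected_amplicon_bp: 93
  - species_label: rainbow_trout
    gene: myoglobin
    accession: NM_001171862
    fwd_primer: TTGCTTGTGACTTCCAGA
    rev_primer: AGAGGAACAACGCACATT
    probe: ACTGGAAAAGTGTATGAGGCAAAGC
    reporter_dye: FAM
    expected_amplicon_bp: 141
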