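>lurae_holotype_22A028 COI barcode, holotype male, Qafa e Lura, Albania
AACATTATATTTTATTTTTGGTATTTGAGCAGGAATAGTAGGAACATCTCTAAGAATTTT
AATTCGTATGGAATTAAGAACTCCTGGATCCTTAATTGGAAATGATCAAATTTATAATAC
TATTGTTACAGCTCATGCATTTATTATAATTTTTTTTATGGTTATACCTATTATAATTGG
AGGATTTGGTAACTGATTAGTTCCCTTAATATTAGGAGCACCTGATATAGCCTTTCCCCG
ATTAAATAATATGAGATTTTGATTATTACCACCATCATTAATACTACTAATTTCTAGAAG
AATTGTAGAAAATGGTGCAGGAACAGGATGAACAGTTTACCCCCCACTTTCATCAAATAT
TGCACATAGAGGATCATCTGTAGATTTAGCAATTTTCTCTCTTCATTTAGCAGGAATTTC
TTCAATTTTAGGAGCAATTAATTTTATTACAACTATCATTAATATACGAGTAAATAATTT
ATCTTTTGATCAAATATCATTATTTATTTGAGCAGTGGGAATTACAGCATTATTATTACT
TTTATCATTGCCTGTATTAGCTGGAGCAATTACCATATTACTAACAGATCGAAACCTTAA
TACCTCATTCTTTGACCCAGCTGGTGGAGGAGATCCAATTTTATATCAACATTTATT
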