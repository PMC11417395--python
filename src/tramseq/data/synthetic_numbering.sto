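# STOCKHOLM 1.0
#=GF CANONICAL_LABELS -1 1 2 3 4 5 6 7 8 9 10 11 12 13 14 15 16 17 18 19 20 20a 20b 21 22 23 24 25 26 27 28 29 30 31 32 33 34 35 36 37 38 39 40 41 42 43 44 45 46 47 48 49 50 51 52 53 54 55 56 57 58 59 60 61 62 63 64 65 66 67 68 69 70 71 72 73 74 75 76
trna00-GAA    -GCGCATTTAGCTCATTTGGG--AGAGCGCCAGACTGAAGATCTGGAG-------------GTCCTGTGTTCGATCCACAGAATTCGCACCA
trna01-GCC    -GCGGATTTAGGTCAGTTGGG--ATAGCGCCAGACAGCCGATCTGGAG-------------GTCCTGTGTTCGATCCACAGAATTCGCACCA
trna02-CTG    -GCGGATTTAGCTCAGTTTGG--AGAGCGCCCGACTCTGGATCTGCAG-------------GTCCTGTGGTCGATCCACAGAATTCGCACCA
trna03-TTG    -GCGGATTTAGCTCAGTTGGG--AGAGAGCCAGACTTTGGACCTGGAG-------------GTCCTGTGTTCGATCCACAGAATTCGCACCA
trna04-GTC    -GCGGATTTAGCTCAGTTGGG--AGAGCGCCAGAGTGTCGATCTGGAG-------------TTCCTGTGTTCTATCCACAGAATTCGCACCA
trna05-CTT    -GCGGCTTTAGCTCAGTTGGG--AGAGCGCCAGACTCTTGATCTTGAG-------------GTCCTGTTTTCGATCCACCGAATTCGCACCA
trna06-TTT    -GCGGATTTAGCTCAGTTGGG--AGAGCGCCAGACTTTTGATCTGGAG-------------GTCTTGTGTTCGATACACAGAATTCGCACCA
trna07-CAT    -GCGGATTGAGCTCAGTTGGG--AGAGCGCCAGACTCATGATCTGGAG-------------GTCCTGTGTTAGATCCACAGACTTCGCACCA
trna08-TGC    -GCGTATTTAGCTCATTTGGG--AGAGCACCAGACTTGCGATCTGGAG-------------GTCCTGTGTTCGATCCAGAGAATTCGCACCA
trna09-AGC    -GCGGATTTAGTTCAGTTGGG--AGAGCGCCAGACTAGCGATCTGGAG-------------GTCCTGTGTTCGATCCACAGAATTGGCACCA
trna10-TCG    -GCGGATATAGCTCAGTTAGG--AGAGCGCCCGACTTCGGATCTGGAG-------------GTCCTGTGTTCGATCCACAGAATTCGCACCA
trna11-GTA    -GCGGATTTAGCTCCGTTGGG--AGAGGGCCAGACTGTAGAGCTGGAG-------------GTCCAGTGTTCGATCCACAGAATTCGCACCA
trna12-CAA    -GCGGATTTAGCTCAGTTGGG--CGAGCGCCAGAGTCAAGATCTGGAG-------------GTCCTGTGTTCGATCCACAGAATTCGCACCA
trna13-AAC    -GCGGATTTAGCTCAGTTGGG--AGAGCGCGAGACTAACGATCTTGAG-------------GTCCTGTATTCGATCCACAGAATTCGCACCA
trna14-TGT    -TCGGATTTAGCTCAGTTGGG--AGAGCGCCAGACTTGTGTTCTGGAG-------------GTCATGTGTTCGATGCACAGAATTCGCACCA
trna15-AGT    -GCGGATTTAGCTCAGTTGGG--AGAGCGCCAGACTAGTGATCTGGAA-------------GTCCTGTGTTGGATCCACAGAATTCGCACCA
trna16-dloop1 -GCGGATTTAGCTCAGTTGGGT-AGAGCGCCAGACTTGCGATCTGGAG-------------GTCCTGTGTTCGATCCACAGAATTCGCACCA
trna17-dloop2 -GCGGATTTAGCTCAGTTGGGTTAGAGCGCCAGACTAGCGATCTGGAG-------------GTCCTGTGTTCGATCCACAGAATTCGCACCA
trna18-ser    -GCGGATTTAGCTCAGTTGGG--AGAGCGCCAGACTGCTGATCTGGAGGGTTCGACTCC--GTCCTGTGTTCGATCCACAGAATTCGCACCA
trna19-leu    -GCGGATTTAGCTCAGTTGGG--AGAGCGCCAGACTCAGGATCTGGAGGGTTCGACTCCGGGTCCTGTGTTCGATCCACAGAATTCGCACCA
trna20-his    GGCGGATTTAGCTCAGTTGGG--AGAGCGCCAGACTGTGGATCTGGAG-------------GTCCTGTGTTCGATCCACAGAATTCGCACCA
#=GC CANON    xxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxxx.............xxxxxxxxxxxxxxxxxxxxxxxxxxxxxxx
//
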