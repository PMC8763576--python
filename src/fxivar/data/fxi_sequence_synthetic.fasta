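>FXI_synthetic_standin 625-residue HGVS-indexed sequence; SYNTHETIC: conserved-Cys topology, catalytic triad, activation site and named variant/interface residue identities are fixed, all other positions are deterministic filler (not the database reference sequence)
MIFLYQVVHFILFTSVSGECHMDVREKSCYVLMGKTLVSHPKEHLCDFFCTHFGSCLGRH
MWLAFLVMQPVVFDECTWLADIIDADHRKQPHEMITGTLAYWCVNQEEYCSLTMGKNFPA
YLIAFHHLIAIIIFECNNPCKGRFLCMATGYDAAQMGIRAFRLNCKRLKWYPDWSIVSWT
DFGIKPGENEGKCQENRMFCHDLGKIDSRDLMLMFWQGGFWLYYYCWDSCTDDGFCARYS
LAIGDWMMSPAIDHCMWSNGKMGPRQWRFQRFAGLDVHTQQICDTKYSRDCDFGIPPLWY
FLASEGDIVGAQKGWSCPDVCHPMTRCVHNLYTIHRYYCNYDLLKCYVKRYEYASETFKL
NKRVNGTGWLTSRCTEGELCPAGGGYRIRTDEAPTRQQLAVDQAMKETFAWNVNWCDITG
GLQNWQLQPWHCIRKQAESTAVRPYHYWSDNPWKLMAPENDSKSWLAAGHVKGLAHKEKD
GTHRTMWLKAAMTEAAEMACVMIDSAKSIMYNACWGVWWPYGDSQQMTPSVSHDAFLHIA
LKLICRYRMTELNKMIRSACWLMHLGIHQDCYIWSMQLFYCSGQFAPWSMYNKEQGGDCF
WGSQQQPESRSKIEWFFYLRWTIER
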