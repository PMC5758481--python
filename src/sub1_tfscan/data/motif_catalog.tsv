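# PLACE-style cis-element catalog: name, IUPAC consensus, category
# Consensi transcribed from the public PLACE compilation of plant
# cis-acting regulatory elements; the two truncated telo-boxes are the
# printed 6/7-mer consensi.  Edit freely: this file is data, not code.
name	iupac	category
GT1CONSENSUS	GRWAAW	hypoxia_light
ANAERO1CONSENSUS	AAACAAA	hypoxia_light
ANAERO2CONSENSUS	AGCAGC	hypoxia_light
ANAERO3CONSENSUS	TCATCAC	hypoxia_light
ANAERO4CONSENSUS	GTTTHGCAA	hypoxia_light
PYRIMIDINEBOXOSRAMY1A	CCTTTT	energy_sugar
TATCCAOSAMY	TATCCA	energy_sugar
CGACGOSAMY3	CGACG	energy_sugar
TATCCAYMOTIFOSRAMY3D	TATCCAY	energy_sugar
CAREOSREP1	CAACTC	energy_sugar
SITEIIATCYTC	TGGGCY	energy_sugar
SITEIIAOSPCNA	TGGGCCCAC	energy_sugar
SITEIIBOSPCNA	TGGTCCCAC	energy_sugar
SITEIOSPCNA	CCACGTGG	energy_sugar
AACACOREOSGLUB1	AACAAAC	energy_sugar
PROLAMINBOXOSGLUB1	TGCAAAG	energy_sugar
GCN4OSGLUB1	TGAGTCA	energy_sugar
ACGTOSGLUB1	GTACGTG	energy_sugar
GARE1OSREP1	TAACAGA	energy_sugar
GARE2OSREP1	TAACGTA	energy_sugar
BP5OSWX	CAACGTG	energy_sugar
BIHD1OS	TGTCA	transcription_cell_division
TATABOXOSPAL	TATTTAA	transcription_cell_division
TATABOX1	CTATAAATAC	transcription_cell_division
E2FCONSENSUS	WTTSSCSS	transcription_cell_division
E2F1OSPCNA	GCGGGAAA	transcription_cell_division
LEAFYATAG	CCAATGT	transcription_cell_division
WUSATAG	TTAATGG	transcription_cell_division
TELOBOXTRUNCATED1	ACCCTA	transcription_cell_division
TELOBOXTRUNCATED2	AAACCCT	transcription_cell_division
DRECRTCOREAT	RCCGAC	hormone_stress
ACGTABREMOTIFA2OSEM	ACGTGKC	hormone_stress
ABREOSRAB21	ACGTSSSC	hormone_stress
IRO2OS	CACGTGG	hormone_stress
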