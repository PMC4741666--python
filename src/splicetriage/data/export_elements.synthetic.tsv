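# SYNTHETIC placeholder table of mRNA nuclear-export regulatory elements.
# The element names follow the published vocabulary (eIF4E-SE, CJE, CAR,
# PRE, CTE, SSCR); the motif sequences below are synthetic stand-ins chosen
# to be long enough not to occur by chance, because the real element
# sequence collection is not redistributable here. Replace via the
# export_table config key to scan a real collection.
name	motif	effect
eIF4E-SE	TGACCGCTAGCA	facilitates
CJE	CCATGGTACGTC	facilitates
CAR	GATCCTAGGACT	facilitates
PRE	ACGGATTCGCAA	facilitates
CTE	TCCGAACGTGGA	facilitates
SSCR	GGCTATCCGTTG	obstructs
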