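source	target	layer_name	category	weight
ABCG1	BCL6	genetic-interaction	7	1.0
AKT1	AR	physical-interaction	2	1.0
AKT1	BRCA1	physical-interaction	2	1.0
AKT1	EP300	physical-interaction	2	1.0
AKT1	ERBB2	co-expression	1	1.0
AKT1	ESR1	physical-interaction	2	1.0
AKT1	MAP2K2	co-expression	1	1.0
AKT1	MTOR	physical-interaction	2	1.0
AKT1	MTOR	pathway	3	1.0
AKT1	MTOR	predicted	4	1.0
AKT1	MTOR	co-localization	5	1.0
AKT1	NCOA1	co-expression	1	1.0
AKT1	NCOA1	pathway	3	1.0
AKT1	PIK3CA	physical-interaction	2	1.0
AKT1	PIK3CA	pathway	3	1.0
AKT1	SMO	pathway	3	1.0
AKT1	TP53	co-expression	1	1.0
APOB	BCL6	co-expression	1	1.0
APOB	BCL6	genetic-interaction	7	1.0
AR	ESR1	physical-interaction	2	1.0
AR	ESR1	pathway	3	1.0
AR	ESR1	co-localization	5	1.0
AR	ESR1	shared-protein-domains	6	1.0
AR	NCOA1	physical-interaction	2	1.0
AR	NCOA1	pathway	3	1.0
AR	TP53	physical-interaction	2	1.0
AR	TP53	genetic-interaction	7	1.0
BCL6	EP300	physical-interaction	2	1.0
BCL6	EP300	genetic-interaction	7	1.0
BCL6	GABRR1	genetic-interaction	7	1.0
BCL6	HDAC5	physical-interaction	2	1.0
BCL6	HDAC5	pathway	3	1.0
BCL6	KLHL24	co-expression	1	1.0
BCL6	PIK3CA	co-expression	1	1.0
BCL6	PTCH1	genetic-interaction	7	1.0
BCL6	SLC10A1	co-expression	1	1.0
BCL6	SMO	physical-interaction	2	1.0
BCL6	TP53	physical-interaction	2	1.0
BCL6	TP53	pathway	3	1.0
BRCA1	ESR1	physical-interaction	2	1.0
BRCA1	ESR1	pathway	3	1.0
BRCA1	NCOA1	physical-interaction	2	1.0
BRCA1	TP53	physical-interaction	2	1.0
BRCA1	TP53	pathway	3	1.0
CASP8	ESR1	genetic-interaction	7	1.0
CASP8	TP53	physical-interaction	2	1.0
CYP1A1	NCOA1	co-expression	1	1.0
DUSP10	NCOA1	co-expression	1	1.0
DUSP10	NCOA1	genetic-interaction	7	1.0
EP300	ESR1	physical-interaction	2	1.0
EP300	ESR1	pathway	3	1.0
EP300	NCOA1	co-expression	1	1.0
EP300	NCOA1	physical-interaction	2	1.0
EP300	NCOA1	pathway	3	1.0
EP300	NCOA1	shared-protein-domains	6	1.0
EP300	TP53	physical-interaction	2	1.0
EP300	TP53	genetic-interaction	7	1.0
ERBB2	ESR1	physical-interaction	2	1.0
ERBB2	TP53	co-expression	1	1.0
ESR1	HDAC5	physical-interaction	2	1.0
ESR1	NCOA1	physical-interaction	2	1.0
ESR1	NCOA1	pathway	3	1.0
ESR1	NCOA7	physical-interaction	2	1.0
ESR1	NCOA7	pathway	3	1.0
ESR1	PIK3CA	physical-interaction	2	1.0
ESR1	PIK3CA	pathway	3	1.0
ESR1	SLC10A1	co-expression	1	1.0
ESR1	SMO	co-expression	1	1.0
ESR1	TP53	physical-interaction	2	1.0
HDAC5	NCOA1	genetic-interaction	7	1.0
HDAC5	TP53	physical-interaction	2	1.0
KLHL24	NCOA1	co-expression	1	1.0
MTOR	TP53	physical-interaction	2	1.0
NCOA1	NCOA7	genetic-interaction	7	1.0
NCOA1	PTCH1	genetic-interaction	7	1.0
NCOA1	TP53	physical-interaction	2	1.0
SMO	TP53	co-expression	1	1.0
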