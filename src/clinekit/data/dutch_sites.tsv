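name	site	lat	lon	n_initial	n_clean
Assen	ASS	53	6.55	17	17
Barneveld	BAR	52.1333	5.58333	20	20
Beilen	BEI	52.8667	6.51667	9	9
Bergen op Zoom	BER	51.5	4.3	18	18
Borger	BOR	52.9167	6.8	7	7
Delfzijl	DEL	53.3333	6.91667	10	10
Denekamp	DEN	52.3833	7	22	19
Dokkum	DOK	53.3333	6	23	23
Drachten	DRA	53.1	6.1	20	20
Druten	DRU	51.8833	5.61667	20	18
Eelde	EEL	53.117	6.583	7	7
Emmen	EMM	52.7833	6.9	9	9
Genemuiden	GEN	52.6333	6.05	16	16
Haaksbergen	HAA	52.15	6.73333	22	21
Harlingen	HAR	53.1833	5.41667	23	20
Heemskerk	HEE	52.5167	4.66667	18	18
Heerhugowaard	HER	52.6667	4.85	21	21
Heerlen	HEL	50.9	5.98333	20	20
Hilversum	HIL	52.2333	5.18333	20	20
Hollum	HOL	53.4167	5.63333	10	8
Hoogeveen	HOO	52.7333	6.48333	24	21
Hoogezand	HOG	53.1667	6.76667	1	1
Hoorn	HOR	52.65	5.06667	20	20
Hulst	HUL	51.283	4.05	21	20
Kampen	KAM	52.55	5.91667	24	24
Kollum	KOL	53.2833	6.15	11	11
Leeuwarden	LEE	53.2	5.78333	23	23
Leiden	LEI	52.15	4.5	68	65
Losser	LOS	52.2667	7.01667	20	20
Maarssenbroek	MAA	52.133	5.033	20	20
Maastricht	MAS	50.85	5.68333	20	19
Markelo	MAR	52.2333	6.5	17	16
Meppel	MEP	52.7	6.2	24	24
Middelburg	MID	51.5	3.617	19	19
Midsland	MIS	53.3833	5.28333	20	20
Mijdrecht	MIJ	52.2	4.86667	20	19
Nes	NES	53.45	5.76667	6	5
Oostburg	OOS	51.333	3.5	18	18
Oss	OSS	51.767	5.534	20	18
Purmerend	PUR	52.5167	4.95	20	19
Roermond	ROE	51.2	6	21	21
Schagen	SCH	52.7833	4.8	20	19
Sittard	SIT	51	5.867	20	20
Steenwijk	STE	52.7833	6.11667	11	11
Ter Apel	TER	52.8833	7.06667	6	6
Tubbergen	TUB	52.4167	6.78333	18	16
Veendam	VEE	53.1	6.88333	19	19
Veghel	VEG	51.6167	5.55	20	20
Waalwijk	WAA	51.6833	5.06667	20	20
Weert	WEE	51.25	5.71667	20	20
Winschoten	WIN	53.15	7.03333	15	15
Woerden	WOE	52.0833	4.91667	21	21
Zaltbommel	ZAL	51.8	5.25	20	20
Zierikzee	ZIE	51.65	3.916	20	18
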