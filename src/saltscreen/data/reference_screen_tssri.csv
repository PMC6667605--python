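genotype,tssri,printed_class
IR85427,25.15,sensitive
75-1-127,25.34,sensitive
IR86126,25.42,sensitive
IRRI 152,25.68,sensitive
IR09F436,26.04,sensitive
CT18372,26.29,sensitive
CT18237,26.30,sensitive
IR78221,26.75,sensitive
IR65482,26.77,low
IR74371,27.68,low
IR06N155,27.78,low
IR78222,27.82,low
IR07F287,27.89,low
IR86052,27.97,low
CT18614,28.07,low
IRRI 123,28.10,low
IR78049,28.11,low
IR08A172,28.11,low
IR09N537,28.14,low
IR04A115,28.41,low
CT6946,28.49,low
IR09L179,28.60,low
HHZ 12,28.68,low
IR05N412,28.73,low
IR75483,28.79,low
IR09L324,28.90,low
FED CARE,28.93,low
IR10N230,28.94,low
Apo,28.99,low
COL XXI,29.07,low
Thad,29.09,low
12DS-15,29.26,low
IR65600,29.31,low
CT19561,29.31,low
IRRI 157,29.40,moderate
IR6-PAK,29.40,moderate
IR09A130,29.49,moderate
MTU1010,29.55,moderate
Geumg,30.01,moderate
IR86174,30.05,moderate
Rex,30.14,moderate
IR49830,30.15,moderate
CT18615,30.21,moderate
CT18244,30.26,moderate
IR85422,30.28,moderate
IR70213,30.48,moderate
IR05F102,30.60,moderate
IR86635,30.60,moderate
IR09L337,30.79,moderate
IR93323,30.95,moderate
IR07K142,31.02,moderate
BR47,31.09,moderate
12DS-25,31.14,moderate
IR64-NIL,31.16,moderate
IR86174,31.17,moderate
IR88633,31.19,moderate
CT18247,31.23,moderate
WAB,31.53,moderate
IR07F102,31.89,moderate
FEDE 21,31.95,moderate
FED 2000,32.16,moderate
Pokalli,32.21,high
IR86174,32.39,high
MIL 240,32.75,high
HHZ 1,33.11,high
IR10A134,33.62,high
PALMAR,34.01,high
IR85411,34.27,high
IR08N136,34.47,high
CT18245,34.48,high
N. B,35.14,high
CT18233,36.39,high
IRRI 154,36.88,high
FED 473,39.87,high
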