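genotype,pc1,pc2,printed_class
75-1-127,-7.20747,-2.66338,sensitive
IR09L179,-5.83758,-0.15216,sensitive
IRRI 152,-4.81707,-1.40919,sensitive
Rex,-4.00992,-0.99713,sensitive
IRRI 123,-3.9105,-1.34373,sensitive
IR86126,-3.86677,-0.98558,sensitive
CT18237,-2.40691,-1.02424,sensitive
IR6-PAK,-2.27069,-1.49439,sensitive
IR78221,-1.9699,-0.15419,sensitive
COL XXI,-1.93097,-1.64531,sensitive
IR65482,-1.71975,-1.04947,sensitive
IR07K142,-1.45877,-0.74953,sensitive
Apo,-1.40352,-1.53399,sensitive
IR09L337,-1.10877,-0.81638,sensitive
FED CARE,-0.69476,-1.78144,sensitive
Thad,-0.61214,-1.73198,sensitive
IR74371,-0.47901,-2.47098,sensitive
CT19561,-0.24034,-0.34978,sensitive
IR78222,-0.03126,-0.62981,sensitive
IR09F436,-6.25998,0.47198,low
IR06N155,-5.7825,0.28962,low
IR09N537,-3.21539,0.90534,low
HHZ 12,-3.10293,1.37628,low
IR10A134,-2.64443,0.76949,low
IR05N412,-2.5097,1.26958,low
CT18372,-2.37581,1.67961,low
IR85427,-1.9708,4.33859,low
12DS-15,-1.96519,1.8158,low
IR75483,-1.70066,0.44658,low
CT18615,-1.56465,0.6572,low
IR09L324,-1.49041,0.84895,low
FEDE 21,-1.34659,0.2753,low
IR08A172,-1.14798,0.24716,low
IR05F102,-0.75738,2.03509,low
CT6946,-0.59829,0.76617,low
Pokalli,-0.56238,2.6694,low
IR88633,-0.26281,0.63098,low
IR65600,-0.14751,0.35194,low
CT18614,-0.13627,4.42101,low
IR49830,0.10374,-1.6559,moderate
IR10N230,0.41738,-0.55351,moderate
IR70213,0.63453,-2.00713,moderate
IR08N136,1.06702,-1.26436,moderate
CT18247,1.26334,-1.2856,moderate
IR07F287,1.90588,-0.02396,moderate
IR86052,2.34044,-0.56439,moderate
MTU1010,2.45831,-1.42011,moderate
FED 2000,2.46614,-1.23379,moderate
IR86174,3.32968,-3.82995,moderate
CT18233,3.8009,-2.67039,moderate
12DS-25,4.7199,-0.41126,moderate
BR47,4.92908,-1.29948,moderate
CT18245,5.4841,-1.58231,moderate
WAB,5.54291,-0.62458,moderate
IR86635,5.93269,-0.52805,moderate
CT18244,0.11701,0.16053,high
IR86174,0.12364,0.0148,high
IR78049,0.21897,0.25885,high
IR09A130,0.39813,0.09956,high
IR93323,0.69812,0.57024,high
IR04A115,1.0283,0.35985,high
MIL 240,1.45441,2.47947,high
N.B,1.73399,4.61212,high
HHZ 1,1.98,1.52945,high
IRRI 157,2.44828,0.73081,high
IR86174,2.46668,0.073,high
IR64-NIL,2.51893,0.22771,high
IRRI 154,2.65546,0.23095,high
IR07F102,2.95038,0.91518,high
Geumg,3.02336,1.12504,high
IR85411,3.05235,0.85483,high
PALMAR 18,4.0456,0.70352,high
IR85422,4.06916,1.24965,high
FED 473,4.13896,1.4758,high
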