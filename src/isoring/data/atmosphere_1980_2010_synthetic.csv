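year,ca,d13c_atm
1980,338.70,-7.500
1981,340.06,-7.519
1982,341.45,-7.539
1983,342.86,-7.560
1984,344.29,-7.581
1985,345.75,-7.603
1986,347.23,-7.626
1987,348.74,-7.649
1988,350.27,-7.672
1989,351.82,-7.697
1990,353.40,-7.722
1991,355.00,-7.748
1992,356.63,-7.774
1993,358.28,-7.801
1994,359.95,-7.829
1995,361.65,-7.857
1996,363.37,-7.886
1997,365.12,-7.915
1998,366.89,-7.946
1999,368.68,-7.977
2000,370.50,-8.008
2001,372.34,-8.040
2002,374.21,-8.073
2003,376.10,-8.106
2004,378.01,-8.140
2005,379.95,-8.175
2006,381.91,-8.210
2007,383.90,-8.246
2008,385.91,-8.283
2009,387.94,-8.320
2010,390.00,-8.358
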