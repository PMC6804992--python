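year,phase,season
1983,ElNino,WS
1987,ElNino,WS
1988,ElNino,WS
1992,ElNino,WS
1993,ElNino,WS
1995,ElNino,WS
1998,ElNino,WS
2003,ElNino,WS
2005,ElNino,WS
2010,ElNino,WS
2015,ElNino,WS
2016,ElNino,WS
1984,LaNina,AW
1985,LaNina,AW
1988,LaNina,AW
1989,LaNina,AW
1996,LaNina,AW
1999,LaNina,AW
2000,LaNina,AW
2001,LaNina,AW
2002,LaNina,AW
2005,LaNina,AW
2008,LaNina,AW
2011,LaNina,AW
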