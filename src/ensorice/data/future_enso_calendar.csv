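year,phase,season
2021,ElNino,WS
2026,ElNino,WS
2027,ElNino,WS
2033,ElNino,WS
2036,ElNino,WS
2038,ElNino,WS
2039,ElNino,WS
2043,ElNino,WS
2047,ElNino,WS
2023,LaNina,AW
2027,LaNina,AW
2028,LaNina,AW
2031,LaNina,AW
2034,LaNina,AW
2035,LaNina,AW
2037,LaNina,AW
2040,LaNina,AW
2041,LaNina,AW
2045,LaNina,AW
2048,LaNina,AW
2049,LaNina,AW
2050,LaNina,AW
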