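province,scenario,season,present,future,d_pct
Long An,RCP4.5,WS,5.86,5.78,1.37
Long An,RCP4.5,SA,4.19,4.12,1.67
Long An,RCP4.5,AW,3.28,3.22,1.83
Long An,RCP8.5,WS,5.86,5.46,6.83
Long An,RCP8.5,SA,4.19,4.00,4.53
Long An,RCP8.5,AW,3.28,3.12,4.88
Tien Giang,RCP4.5,WS,6.71,6.58,1.94
Tien Giang,RCP4.5,SA,4.94,4.84,2.02
Tien Giang,RCP4.5,AW,4.42,4.35,1.58
Tien Giang,RCP8.5,WS,6.71,6.28,6.41
Tien Giang,RCP8.5,SA,4.94,4.71,4.66
Tien Giang,RCP8.5,AW,4.42,4.20,4.98
Ben Tre,RCP4.5,WS,4.99,4.89,2.00
Ben Tre,RCP4.5,SA,4.11,4.04,1.70
Ben Tre,RCP4.5,AW,4.16,4.09,1.68
Ben Tre,RCP8.5,WS,4.99,4.67,6.41
Ben Tre,RCP8.5,SA,4.11,3.94,4.14
Ben Tre,RCP8.5,AW,4.16,3.98,4.33
Tra Vinh,RCP4.5,WS,5.54,5.44,1.81
Tra Vinh,RCP4.5,SA,4.84,4.77,1.45
Tra Vinh,RCP4.5,AW,4.67,4.61,1.28
Tra Vinh,RCP8.5,WS,5.54,5.18,6.50
Tra Vinh,RCP8.5,SA,4.84,4.62,4.55
Tra Vinh,RCP8.5,AW,4.67,4.46,4.50
Vinh Long,RCP4.5,WS,6.58,6.48,1.52
Vinh Long,RCP4.5,SA,4.75,4.68,1.47
Vinh Long,RCP4.5,AW,4.43,4.37,1.35
Vinh Long,RCP8.5,WS,6.58,6.17,6.23
Vinh Long,RCP8.5,SA,4.75,4.56,4.00
Vinh Long,RCP8.5,AW,4.43,4.24,4.29
Dong Thap,RCP4.5,WS,6.99,6.83,2.29
Dong Thap,RCP4.5,SA,5.23,5.12,2.10
Dong Thap,RCP4.5,AW,4.32,4.26,1.39
Dong Thap,RCP8.5,WS,6.99,6.53,6.58
Dong Thap,RCP8.5,SA,5.23,5.01,4.21
Dong Thap,RCP8.5,AW,4.32,4.09,5.32
An Giang,RCP4.5,WS,7.29,7.15,1.92
An Giang,RCP4.5,SA,4.84,4.75,1.86
An Giang,RCP4.5,AW,4.46,4.37,2.02
An Giang,RCP8.5,WS,7.29,6.82,6.45
An Giang,RCP8.5,SA,4.84,4.58,5.37
An Giang,RCP8.5,AW,4.46,4.19,6.05
Kien Giang,RCP4.5,WS,6.68,6.53,2.25
Kien Giang,RCP4.5,SA,4.86,4.77,1.85
Kien Giang,RCP4.5,AW,4.07,4.01,1.47
Kien Giang,RCP8.5,WS,6.68,6.23,6.74
Kien Giang,RCP8.5,SA,4.86,4.62,4.94
Kien Giang,RCP8.5,AW,4.07,3.87,4.91
Can Tho,RCP4.5,WS,7.06,6.93,1.84
Can Tho,RCP4.5,SA,4.70,4.62,1.70
Can Tho,RCP4.5,AW,3.89,3.83,1.54
Can Tho,RCP8.5,WS,7.06,6.64,5.95
Can Tho,RCP8.5,SA,4.70,4.51,4.04
Can Tho,RCP8.5,AW,3.89,3.72,4.37
Hau Giang,RCP4.5,WS,6.69,6.58,1.64
Hau Giang,RCP4.5,SA,4.53,4.46,1.55
Hau Giang,RCP4.5,AW,4.46,4.38,1.79
Hau Giang,RCP8.5,WS,6.69,6.30,5.83
Hau Giang,RCP8.5,SA,4.53,4.36,3.75
Hau Giang,RCP8.5,AW,4.46,4.29,3.81
Soc Trang,RCP4.5,WS,6.13,5.98,2.45
Soc Trang,RCP4.5,SA,4.84,4.75,1.86
Soc Trang,RCP4.5,AW,4.46,4.37,2.02
Soc Trang,RCP8.5,WS,6.13,5.75,6.20
Soc Trang,RCP8.5,SA,4.84,4.58,5.37
Soc Trang,RCP8.5,AW,4.46,4.22,5.38
Bac Lieu,RCP4.5,WS,6.27,6.14,2.07
Bac Lieu,RCP4.5,SA,5.10,5.01,1.76
Bac Lieu,RCP4.5,AW,4.82,4.72,2.07
Bac Lieu,RCP8.5,WS,6.27,5.87,6.38
Bac Lieu,RCP8.5,SA,5.10,4.90,3.92
Bac Lieu,RCP8.5,AW,4.82,4.60,4.56
Ca Mau,RCP4.5,SA,4.18,4.11,1.67
Ca Mau,RCP4.5,AW,3.76,3.70,1.60
Ca Mau,RCP8.5,SA,4.18,3.98,4.78
Ca Mau,RCP8.5,AW,3.76,3.59,4.52
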