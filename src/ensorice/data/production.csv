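province,present,rcp45_no_enso,rcp85_no_enso,rcp45_elnino,rcp45_lanina,rcp85_elnino,rcp85_lanina
Long An,2.53,2.49,2.38,2.26,2.42,2.16,2.32
Tien Giang,1.18,1.16,1.12,1.14,1.12,1.10,1.08
Ben Tre,0.20,0.19,0.18,0.10,0.19,0.10,0.18
Tra Vinh,1.14,1.12,1.08,0.78,1.12,0.75,1.08
Vinh Long,0.93,0.92,0.88,0.87,0.90,0.84,0.87
Dong Thap,3.12,3.05,2.95,3.05,2.69,2.95,2.60
An Giang,3.75,3.68,3.53,3.68,3.19,3.53,3.06
Kien Giang,4.20,4.12,3.96,3.58,4.08,3.45,3.92
Can Tho,1.27,1.25,1.21,1.25,1.15,1.21,1.11
Hau Giang,1.12,1.10,1.07,0.86,0.96,0.83,0.93
Soc Trang,1.93,1.89,1.82,1.53,1.89,1.48,1.82
Bac Lieu,0.96,0.94,0.92,0.89,0.94,0.87,0.92
Ca Mau,0.46,0.45,0.44,0.45,0.44,0.44,0.43
MRD,22.79,22.37,21.52,20.45,21.12,19.69,20.32
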