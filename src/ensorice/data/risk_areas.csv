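province,hazard,high,medium,low,none
Long An,salinity,15.4,11.7,21.2,51.7
Tien Giang,salinity,2.1,0.2,47.3,50.4
Ben Tre,salinity,87.8,0.6,0.0,11.6
Tra Vinh,salinity,53.4,28.9,16.9,0.9
Vinh Long,salinity,8.1,20.5,28.3,43.1
Dong Thap,salinity,0.0,0.0,0.0,100.0
An Giang,salinity,0.0,0.0,11.1,88.9
Kien Giang,salinity,25.9,0.4,0.0,73.8
Can Tho,salinity,0.0,0.0,0.0,100.0
Hau Giang,salinity,45.8,4.1,10.6,39.5
Soc Trang,salinity,27.1,39.3,0.7,32.9
Bac Lieu,salinity,10.7,19.0,48.3,22.0
Ca Mau,salinity,75.9,2.4,0.0,21.7
Long An,flood,16.2,60.9,0.0,22.9
Tien Giang,flood,26.8,16.2,2.0,55.0
Ben Tre,flood,0.0,0.0,0.0,100.0
Tra Vinh,flood,0.0,0.0,0.1,99.9
Vinh Long,flood,0.0,38.4,28.3,33.2
Dong Thap,flood,47.9,41.6,3.8,6.8
An Giang,flood,55.2,15.1,0.0,29.7
Kien Giang,flood,0.0,28.2,66.7,5.1
Can Tho,flood,27.2,29.4,16.9,26.5
Hau Giang,flood,59.2,8.9,31.8,0.0
Soc Trang,flood,0.0,0.0,0.0,100.0
Bac Lieu,flood,0.0,0.0,0.0,100.0
Ca Mau,flood,0.0,25.3,0.0,74.7
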