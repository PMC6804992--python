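province,scenario,dt,drain_pct
Long An,RCP4.5,1.4,12.5
Tien Giang,RCP4.5,1.4,13.0
Ben Tre,RCP4.5,1.4,18.2
Tra Vinh,RCP4.5,1.4,15.5
Vinh Long,RCP4.5,1.4,13.5
Dong Thap,RCP4.5,1.4,11.0
An Giang,RCP4.5,1.4,10.5
Kien Giang,RCP4.5,1.4,9.5
Can Tho,RCP4.5,1.4,14.0
Hau Giang,RCP4.5,1.4,14.5
Soc Trang,RCP4.5,1.4,16.0
Bac Lieu,RCP4.5,1.4,12.0
Ca Mau,RCP4.5,1.4,5.8
Long An,RCP8.5,1.85,13.5
Tien Giang,RCP8.5,1.85,14.0
Ben Tre,RCP8.5,1.85,17.5
Tra Vinh,RCP8.5,1.85,16.0
Vinh Long,RCP8.5,1.85,14.5
Dong Thap,RCP8.5,1.85,13.0
An Giang,RCP8.5,1.85,12.5
Kien Giang,RCP8.5,1.85,11.5
Can Tho,RCP8.5,1.85,18.3
Hau Giang,RCP8.5,1.85,15.5
Soc Trang,RCP8.5,1.85,16.5
Bac Lieu,RCP8.5,1.85,13.5
Ca Mau,RCP8.5,1.85,10.8
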