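province,phase,level,d_lower,d_upper,d
Long An,ElNino,high,15,100,15
Long An,ElNino,medium,4,14,14
Long An,ElNino,low,0,3,3
Tien Giang,ElNino,high,12,100,12
Tien Giang,ElNino,medium,3,11,11
Tien Giang,ElNino,low,0,2,2
Ben Tre,ElNino,high,50,100,50
Ben Tre,ElNino,medium,10,49,49
Ben Tre,ElNino,low,0,9,9
Tra Vinh,ElNino,high,46,100,46
Tra Vinh,ElNino,medium,9,45,45
Tra Vinh,ElNino,low,0,8,8
Vinh Long,ElNino,high,17,100,17
Vinh Long,ElNino,medium,4,16,16
Vinh Long,ElNino,low,0,3,3
An Giang,ElNino,high,10,100,10
An Giang,ElNino,medium,2,9,9
An Giang,ElNino,low,0,1,1
Kien Giang,ElNino,high,21,100,21
Kien Giang,ElNino,medium,5,20,20
Kien Giang,ElNino,low,0,4,4
Hau Giang,ElNino,high,25,100,25
Hau Giang,ElNino,medium,5,24,24
Hau Giang,ElNino,low,0,4,4
Soc Trang,ElNino,high,34,100,34
Soc Trang,ElNino,medium,6,33,33
Soc Trang,ElNino,low,0,5,5
Bac Lieu,ElNino,high,28,100,28
Bac Lieu,ElNino,medium,5,27,27
Bac Lieu,ElNino,low,0,4,4
Long An,LaNina,high,25,100,25
Long An,LaNina,medium,4,24,24
Long An,LaNina,low,0,3,3
Tien Giang,LaNina,high,17,100,17
Tien Giang,LaNina,medium,3,16,16
Tien Giang,LaNina,low,0,2,2
Vinh Long,LaNina,high,14,100,14
Vinh Long,LaNina,medium,3,13,13
Vinh Long,LaNina,low,0,2,2
An Giang,LaNina,high,26,100,26
An Giang,LaNina,medium,5,25,25
An Giang,LaNina,low,0,4,4
Kien Giang,LaNina,high,18,100,18
Kien Giang,LaNina,medium,3,17,17
Kien Giang,LaNina,low,0,2,2
Ca Mau,LaNina,high,12,100,12
Ca Mau,LaNina,medium,3,11,11
Ca Mau,LaNina,low,0,2,2
Can Tho,LaNina,high,20,100,20
Can Tho,LaNina,medium,3,19,19
Can Tho,LaNina,low,0,2,2
Dong Thap,LaNina,high,25,100,25
Dong Thap,LaNina,medium,4,24,24
Dong Thap,LaNina,low,0,3,3
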