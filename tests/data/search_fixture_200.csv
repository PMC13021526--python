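participant,block,trial_index,target_location,distractor_location,hp_location,rt,correct
s1,1,1,0,5,0,979.0,True
s1,1,2,1,2,0,607.0,True
s1,1,3,2,,0,539.8,True
s1,1,4,3,4,0,567.3,True
s1,1,5,4,,0,300.0,False
s1,1,6,5,1,0,557.7,True
s1,1,7,6,1,0,871.9,True
s1,1,8,7,0,0,504.1,False
s1,1,9,0,,0,762.3,True
s1,1,10,1,,0,2000.0,True
s1,1,11,2,7,0,463.7,True
s1,1,12,3,,0,625.5,True
s1,1,13,4,0,0,698.2,True
s1,1,14,5,0,0,943.8,True
s1,1,15,6,7,0,250.0,True
s1,1,16,7,,0,951.2,True
s1,1,17,0,1,0,651.2,True
s1,1,18,1,0,0,534.0,True
s1,1,19,2,7,0,898.6,True
s1,1,20,3,0,0,5000.0,True
s1,1,21,4,,0,783.8,True
s1,1,22,5,0,0,698.9,True
s1,1,23,6,,0,131.3,True
s1,1,24,7,6,0,640.4,True
s1,1,25,0,3,0,450.5,True
s1,1,26,1,0,0,757.9,True
s1,1,27,2,6,0,619.6,True
s1,1,28,3,,0,677.3,True
s1,1,29,4,1,0,681.1,True
s1,2,30,5,1,0,732.8,False
s1,2,31,6,5,0,726.4,True
s1,2,32,7,5,0,666.4,True
s1,2,33,0,5,0,750.0,True
s1,2,34,1,2,0,453.4,True
s1,2,35,2,6,0,749.8,True
s1,2,36,3,4,0,917.1,True
s1,2,37,4,7,0,660.2,False
s1,2,38,5,,0,595.4,True
s1,2,39,6,3,0,786.9,True
s1,2,40,7,5,0,790.9,False
s1,2,41,0,5,0,903.2,True
s1,2,42,1,0,0,701.0,True
s1,2,43,2,,0,1017.1,True
s1,2,44,3,4,0,851.6,False
s1,2,45,4,3,0,940.4,False
s1,2,46,5,3,0,1118.5,True
s1,2,47,6,0,0,888.1,True
s1,2,48,7,0,0,690.3,True
s1,2,49,0,6,0,841.7,True
s1,2,50,1,3,0,679.8,True
s1,2,51,2,4,0,435.1,True
s1,2,52,3,5,0,656.6,True
s1,2,53,4,5,0,1035.0,True
s1,2,54,5,0,0,776.2,True
s1,2,55,6,0,0,649.1,True
s1,2,56,7,6,0,950.0,True
s1,2,57,0,,0,836.7,True
s1,2,58,1,6,0,631.9,True
s1,3,59,2,6,0,619.2,True
s1,3,60,3,6,0,662.9,True
s1,3,61,4,2,0,676.9,True
s1,3,62,5,4,0,738.8,False
s1,3,63,6,0,0,571.2,True
s1,3,64,7,0,0,607.7,True
s1,3,65,0,,0,480.2,True
s1,3,66,1,5,0,736.6,True
s1,3,67,2,0,0,518.9,True
s1,3,68,3,2,0,795.2,False
s1,3,69,4,1,0,779.9,True
s1,3,70,5,4,0,1186.3,False
s1,3,71,6,4,0,800.0,True
s1,3,72,7,,0,973.5,True
s1,3,73,0,1,0,554.6,True
s1,3,74,1,,0,800.4,True
s1,3,75,2,0,0,717.7,False
s1,3,76,3,,0,550.2,True
s1,3,77,4,3,0,851.3,True
s1,3,78,5,4,0,676.6,True
s1,3,79,6,,0,587.3,True
s1,3,80,7,3,0,536.3,True
s1,3,81,0,4,0,2770.8,True
s1,3,82,1,,0,677.6,True
s1,3,83,2,3,0,810.1,True
s1,3,84,3,4,0,-38.7,True
s1,3,85,4,3,0,516.3,True
s1,3,86,5,4,0,740.1,True
s1,3,87,6,5,0,543.4,True
s1,4,88,7,1,0,902.6,False
s1,4,89,0,1,0,791.6,True
s1,4,90,1,6,0,616.2,True
s1,4,91,2,7,0,769.1,True
s1,4,92,3,7,0,843.2,True
s1,4,93,4,2,0,663.9,True
s1,4,94,5,1,0,503.4,True
s1,4,95,6,0,0,815.5,True
s1,4,96,7,0,0,850.6,True
s1,4,97,0,5,0,824.1,False
s1,4,98,1,6,0,670.0,True
s1,4,99,2,,0,629.3,True
s1,4,100,3,4,0,853.8,True
s1,4,101,4,,0,523.7,True
s1,4,102,5,1,0,641.4,True
s1,4,103,6,3,0,552.7,True
s1,4,104,7,0,0,646.3,True
s1,4,105,0,5,0,938.3,False
s1,4,106,1,2,0,726.4,False
s1,4,107,2,,0,750.5,True
s1,4,108,3,0,0,888.3,True
s1,4,109,4,5,0,617.8,False
s1,4,110,5,1,0,575.7,True
s1,4,111,6,4,0,544.8,False
s1,4,112,7,1,0,450.6,True
s1,4,113,0,,0,675.2,True
s1,4,114,1,3,0,674.0,True
s1,4,115,2,1,0,503.3,True
s1,4,116,3,,0,826.8,True
s1,5,117,4,,0,607.9,True
s1,5,118,5,,0,244.4,True
s1,5,119,6,3,0,716.7,True
s1,5,120,7,2,0,559.7,True
s2,1,1,0,2,4,496.5,True
s2,1,2,1,7,4,873.6,False
s2,1,3,2,0,4,692.2,True
s2,1,4,3,4,4,2099.1,True
s2,1,5,4,2,4,510.5,True
s2,1,6,5,6,4,926.1,True
s2,1,7,6,,4,596.8,True
s2,1,8,7,5,4,642.9,False
s2,1,9,0,,4,710.5,True
s2,1,10,1,5,4,769.5,False
s2,1,11,2,3,4,649.1,True
s2,1,12,3,6,4,641.8,True
s2,1,13,4,,4,1036.0,True
s2,1,14,5,6,4,760.2,False
s2,1,15,6,,4,833.9,True
s2,1,16,7,1,4,910.0,True
s2,1,17,0,5,4,719.7,True
s2,1,18,1,0,4,623.1,True
s2,1,19,2,5,4,401.4,True
s2,1,20,3,5,4,521.5,True
s2,1,21,4,,4,935.8,True
s2,1,22,5,4,4,693.4,False
s2,1,23,6,4,4,1130.0,True
s2,1,24,7,1,4,405.0,True
s2,1,25,0,3,4,731.4,True
s2,1,26,1,5,4,647.4,True
s2,1,27,2,6,4,659.5,True
s2,1,28,3,0,4,916.3,True
s2,1,29,4,0,4,360.7,True
s2,2,30,5,0,4,792.8,True
s2,2,31,6,2,4,791.1,True
s2,2,32,7,0,4,286.8,True
s2,2,33,0,4,4,729.6,False
s2,2,34,1,4,4,567.9,True
s2,2,35,2,0,4,769.6,True
s2,2,36,3,1,4,532.1,True
s2,2,37,4,7,4,804.9,True
s2,2,38,5,4,4,606.3,True
s2,2,39,6,1,4,853.6,True
s2,2,40,7,5,4,1017.6,True
s2,2,41,0,5,4,699.0,True
s2,2,42,1,,4,570.2,True
s2,2,43,2,7,4,543.1,True
s2,2,44,3,,4,889.2,True
s2,2,45,4,2,4,576.8,True
s2,2,46,5,2,4,573.7,True
s2,2,47,6,2,4,655.5,True
s2,2,48,7,2,4,661.5,True
s2,2,49,0,2,4,954.4,True
s2,2,50,1,7,4,546.4,True
s2,2,51,2,7,4,907.3,True
s2,2,52,3,0,4,697.8,False
s2,2,53,4,6,4,921.9,True
s2,2,54,5,2,4,484.8,True
s2,2,55,6,4,4,810.0,True
s2,2,56,7,0,4,622.0,True
s2,2,57,0,3,4,532.6,False
s2,2,58,1,7,4,1037.6,True
s2,3,59,2,7,4,607.0,False
s2,3,60,3,0,4,958.5,True
s2,3,61,4,2,4,617.0,True
s2,3,62,5,3,4,768.0,False
s2,3,63,6,3,4,916.3,True
s2,3,64,7,2,4,569.0,True
s2,3,65,0,3,4,428.3,True
s2,3,66,1,3,4,694.3,True
s2,3,67,2,3,4,693.2,True
s2,3,68,3,7,4,314.0,False
s2,3,69,4,7,4,1039.2,False
s2,3,70,5,0,4,817.2,True
s2,3,71,6,7,4,451.2,False
s2,3,72,7,3,4,753.5,False
s2,3,73,0,3,4,868.2,True
s2,3,74,1,6,4,628.4,False
s2,3,75,2,6,4,361.1,True
s2,3,76,3,6,4,528.3,True
s2,3,77,4,6,4,758.7,True
s2,3,78,5,2,4,1034.6,True
s2,3,79,6,4,4,939.1,True
s2,3,80,7,4,4,754.4,True
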