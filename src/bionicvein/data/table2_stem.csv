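no,beta1,beta2,beta3,theta1,theta2,theta3,l1,l2,l3,m1,m2,m3,u1,u2,u3,t1,t2,t3
1,130,130,140,120,125,130,27,33,46,19,25,37,8,11,12,7.5,9,13
2,135,130,135,125,125,140,25,29,45,20,23,35,7,8,10,7.5,8.5,9.5
3,132,130,129,127,135,140,26,30,35,20,24,30,8,9,11,7.5,9,9
4,128,125,123,125,130,132,25,30,35,21,26,33,8,11,12,7.5,9,10
5,130,125,132,120,133,136,24,27,35,17,22,29,8,10,11,7.5,8,9
6,126,123,126,126,137,139,20,22,29,18,23,26,7,9,9,7,7,8
7,126,129,122,122,135,123,20,25,32,18,21,30,7,8,9,7,7,8
8,129,129,119,137,145,132,17,22,29,18,23,26,7,6,9,7,6,6
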