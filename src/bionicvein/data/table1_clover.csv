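no,alpha4,alpha5,alpha6,alpha7,alpha8,alpha9,alpha10,alpha11,alpha12,alpha13,alpha14,alpha15,alpha16,alpha17,h3,h4,l5,l6,m5,m6,l7,m7,l8,m8,u4,t4,u5,t5,u6,t6,u7,t7
1,90,90,90,90,90,90,90,90,90,90,90,90,90,90,9,8,5,10,5,10,5,5,3,3,5,5,3,3,5,5,3,3
2,85,85,120,120,70,70,100,100,70,70,100,100,70,70,10,7,7,10,7,10,4,4,3,3,4,4,3,3,4,4,3,3
3,85,85,140,140,60,60,110,110,70,70,110,110,70,70,9,9,5,8,5,8,4,2,4,2,4,2,4,2,4,2,4,2
4,90,90,150,150,60,60,90,90,60,60,90,90,60,60,5,6,3,8,3,8,4,4,1,1,3,3,2,2,3,3,2,2
5,110,110,120,120,70,70,140,140,70,70,140,140,70,70,9,8,5,12,5,12,4,4,1,1,5,5,1,1,5,5,1,1
6,110,120,120,120,70,80,120,120,70,70,110,110,60,60,6,4,6,10,6,10,3,3,2,2,4,4,3,3,4,4,3,3
7,80,80,110,110,110,110,110,110,110,110,110,110,110,110,9,8,5,5,3,3,5,5,3,3,5,5,3,3,5,5,3,3
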