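fm_id,psi_plus,psi_minus,uui,rank
FM1,0,1.154527,0.132745,1
FM2,0.609973,0.556959,0.022556,7
FM3,0.609973,0.556959,0.022556,7
FM4,0.885972,0.2687,-0.02936,13
FM5,0.797434,0.363282,-0.01246,12
FM6,0.247143,0.936935,0.09092,2
FM7,1.130652,0.036898,-0.07265,20
FM8,0.97508,0.216304,-0.04144,16
FM9,0.972375,0.217421,-0.04113,15
FM10,0.526939,0.63222,0.036856,4
FM11,0.346939,0.81064,0.069612,3
FM12,0.609973,0.556959,0.022559,5
FM13,0.609973,0.556959,0.022556,6
FM14,0.662005,0.502484,0.012754,9
FM15,1.12701,0.037177,-0.07237,19
FM16,0.92424,0.2343,-0.03592,14
FM17,1.044711,0.110589,-0.05833,18
FM18,0.787255,0.378574,-0.01001,11
FM19,0.813468,0.425604,-0.00639,10
FM20,1.02322,0.143807,-0.05305,17
SUM,14.70433,8.697298,0.132745,
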