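fm_id,aras_k,vikor_1mq,waspas_k
FM1,1,0.886001,0.908328
FM2,0.639173,0.490006,0.61668
FM3,0.639173,0.490006,0.61668
FM4,0.547233,0.227734,0.525401
FM5,0.641408,0.256854,0.574432
FM6,0.820733,0.788539,0.768887
FM7,0.449923,0.023046,0.427602
FM8,0.597983,0.094016,0.505932
FM9,0.597983,0.097349,0.505932
FM10,0.697882,0.52666,0.669031
FM11,0.800098,0.653339,0.746237
FM12,0.639173,0.490006,0.61668
FM13,0.639173,0.490006,0.61668
FM14,0.618537,0.443694,0.596717
FM15,0.41857,0.060223,0.408149
FM16,0.556623,0.170121,0.527339
FM17,0.477278,0.097572,0.464974
FM18,0.656759,0.250875,0.594369
FM19,0.732604,0.158472,0.661489
FM20,0.519892,0.085798,0.488624
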