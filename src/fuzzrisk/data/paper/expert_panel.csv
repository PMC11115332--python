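expert,fm_id,optimistic,neutral,pessimistic,defuzzified
Expert 1,FM1,5,7,9,7
Expert 1,FM2,3,5,5,4.67
Expert 1,FM3,3,5,5,4.67
Expert 1,FM4,1,3,3,2.67
Expert 1,FM5,1,3,5,3
Expert 1,FM6,5,7,7,6.67
Expert 1,FM7,1,3,3,2.67
Expert 1,FM8,1,3,3,2.67
Expert 1,FM9,1,3,3,2.67
Expert 1,FM10,3,5,9,5.33
Expert 1,FM11,3,7,9,6.67
Expert 1,FM12,3,5,7,5
Expert 1,FM13,3,5,5,4.67
Expert 1,FM14,3,3,5,3.33
Expert 1,FM15,1,1,3,1.33
Expert 1,FM16,1,3,3,2.67
Expert 1,FM17,1,1,3,1.33
Expert 1,FM18,1,3,5,3
Expert 1,FM19,3,3,5,3.33
Expert 1,FM20,1,1,3,1.33
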