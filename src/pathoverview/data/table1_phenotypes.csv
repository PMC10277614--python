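patient,region,CD20,CD79A,CD3,BCL2,CD56,CD10,BCL6,MUM1,CD138,CD30,EBER,ig
CRUK0701,R1,+,+,#,+,-,-,#,+,#,+,+,K
CRUK0704,T1 IR,+,+,#,+,-,-,#,+,#,+,+,L (K)
CRUK0731,IR,+,+,#,+,-,-,#,+,#,+,+,K
CRUK0764,IR,+,+,-,+,-,-,#,+,#,+,+,L
CRUK0795,IR,+,+,#,+,-,-,#,+,#,+,+,L (K)
CRUK0825,R7,+,+,+,+,-,-,#,+,#,+,+,K
CRUK0830,R4,+,+,#,+,#,-,#,+,#,+,+,K (L)
CRUK0934,R6,+,+,-,+,-,-,#,+,#,+,+,K
CRUK0941,R1,+,+,#,+,-,-,#,+,#,+,+,K (L)
CRUK0949,R6,+,+,+,+,-,-,#,+,#,+,+,K
CRUK0810,R4,+,+,-,+,-,-,#,+,#,+,+,K
CRUK0810,R8,+,+,#,+,-,-,#,+,#,+,+,L (K)
CRUK1054,R2,+,+,#,+,-,-,#,+,#,+,+,K
CRUK1054,R5,+,+,-,+,-,-,#,+,#,+,+,L
CRUK0733,R5,+,+,#,+,-,-,#,+,#,+,+,K
CRUK0733,R1,unavailable,unavailable,unavailable,unavailable,unavailable,unavailable,unavailable,unavailable,unavailable,unavailable,unavailable,unavailable
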