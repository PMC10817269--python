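treatment,trait,mean,se,stars
Jacg16,Pn,1.57,0.06,
Jacg16,Gs,0.023,0.001,
Jacg16,Ci,322.17,4.37,***
Jacg16,Tr,0.95,0.01,
Jacg21,Pn,2.45,0.32,*
Jacg21,Gs,0.019,0.004,
Jacg21,Ci,214.01,3.12,
Jacg21,Tr,1.00,0.02,
Jacg37,Pn,3.22,0.03,**
Jacg37,Gs,0.036,0.001,***
Jacg37,Ci,280.97,1.73,*
Jacg37,Tr,1.72,0.01,***
Jacg81,Pn,3.53,0.08,***
Jacg81,Gs,0.026,0.007,*
Jacg81,Ci,207.72,8.04,
Jacg81,Tr,1.16,0.03,*
Jacg121,Pn,3.58,0.12,***
Jacg121,Gs,0.046,0.003,***
Jacg121,Ci,303.57,4.77,**
Jacg121,Tr,2.25,0.01,***
Jacg189,Pn,1.93,0.02,
Jacg189,Gs,0.035,0.003,**
Jacg189,Ci,327.84,0.94,***
Jacg189,Tr,1.59,0.01,**
Jacg243,Pn,1.47,0.04,
Jacg243,Gs,0.020,0.001,
Jacg243,Ci,261.70,3.00,
Jacg243,Tr,0.98,0.01,
Chcg57,Pn,2.30,0.08,
Chcg57,Gs,0.024,0.007,
Chcg57,Ci,280.65,1.61,*
Chcg57,Tr,1.20,0.03,*
CK,Pn,1.08,0.01,
CK,Gs,0.008,0.001,
CK,Ci,161.93,3.55,
CK,Tr,0.93,0.01,
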