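treatment,CI1,CI2,CI3
Jacg16,-0.083,-0.382,-1.990
Jacg21,-0.118,-1.057,-0.437
Jacg37,0.555,-0.492,-0.107
Jacg81,0.188,-1.574,1.465
Jacg121,1.991,0.511,0.417
Jacg189,0.319,1.792,0.337
Jacg243,-0.454,0.230,-0.627
Chcg57,-0.704,0.580,-0.060
CK,-1.693,0.393,1.002
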