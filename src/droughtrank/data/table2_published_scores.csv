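treatment,mu1,mu2,mu3,D,rank
Jacg16,0.437,0.354,0.000,0.386,6
Jacg21,0.427,0.154,0.450,0.391,5
Jacg37,0.610,0.321,0.545,0.564,3
Jacg81,0.510,0.000,1.000,0.483,4
Jacg121,1.000,0.619,0.697,0.919,1
Jacg189,0.546,1.000,0.673,0.621,2
Jacg243,0.336,0.536,0.394,0.369,7
Chcg57,0.268,0.640,0.559,0.347,8
CK,0.000,0.584,0.866,0.160,9
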