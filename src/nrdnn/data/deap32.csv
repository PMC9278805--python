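region,channel
Frontal,Fp1
Frontal,Fp2
Frontal,AF3
Frontal,AF4
Frontal,F7
Frontal,F3
Frontal,Fz
Frontal,F4
Frontal,F8
Temporal,T7
Temporal,T8
Central,FC5
Central,FC1
Central,FC2
Central,FC6
Central,C3
Central,Cz
Central,C4
Parietal,CP1
Parietal,CP2
Parietal,CP5
Parietal,CP6
Parietal,P7
Parietal,P3
Parietal,Pz
Parietal,P4
Parietal,P8
Parietal,PO3
Parietal,PO4
Occipital,O1
Occipital,Oz
Occipital,O2
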