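freesurfer_name,structure,hemisphere
Left-Hippocampus,hippocampus,left
Right-Hippocampus,hippocampus,right
Left-Thalamus-Proper,thalamus,left
Right-Thalamus-Proper,thalamus,right
Left-Thalamus,thalamus,left
Right-Thalamus,thalamus,right
Left-Amygdala,amygdala,left
Right-Amygdala,amygdala,right
Left-Caudate,caudate,left
Right-Caudate,caudate,right
Left-Putamen,putamen,left
Right-Putamen,putamen,right
Left-Pallidum,pallidum,left
Right-Pallidum,pallidum,right
Left-Accumbens-area,accumbens,left
Right-Accumbens-area,accumbens,right
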