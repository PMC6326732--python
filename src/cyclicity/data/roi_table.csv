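name,x,y,z,network
L amygdala,-17,-2,-24,Limbic
L anterior insula,-36,3,7,Attention control
L cuneus,-4,-88,16,Visual
L frontal eye field,-25,-11,54,Dorsal attention
L inferior frontal lobe,-41,6,10,Attention control
L inferior parietal lobe,-31,68,32,Default mode
L mid frontal gyrus,-39,11,38,Attention control
L parahippocampus,-24,-22,-24,Limbic
L posterior intraparietal sulcus,26,-62,53,Dorsal attention
L primary auditory cortex,55,-27,9,Auditory
L primary visual cortex,-11,-84,1,Visual
L superior occipital lobe,-12,-80,23,Visual
L superior temporal junction,-49,-53,28,Ventral attention
L superior temporal sulcus,-56,-52,9,Ventral attention
L ventral intraparietal sulcus,-30,-83,13,Dorsal attention
Medial prefrontal cortex,8,59,19,Default mode
Posterior cingulate cortex,-2,-50,25,Default mode
Precuneus,0,-56,50,Default mode
R amygdala,18,-7,-17,Limbic
R anterior insula,36,3,7,Attention control
R cuneus,4,-88,16,Visual
R frontal eye field,27,11,54,Dorsal attention
R inferior frontal lobe,45,-4,13,Attention control
R inferior parietal lobe,40,-67,32,Default mode
R mid frontal gyrus,39,11,38,Attention control
R parahippocampus,23,-21,-20,Limbic
R posterior intraparietal sulcus,-23,-70,46,Dorsal attention
R primary auditory cortex,-41,-27,6,Auditory
R primary visual cortex,11,-84,1,Visual
R superior occipital lobe,15,-79,23,Visual
R superior temporal junction,49,-53,28,Ventral attention
R superior temporal sulcus,56,-52,9,Ventral attention
R ventral intraparietal sulcus,30,-83,13,Dorsal attention
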