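# Putative ancestral insect mitochondrial gene order (Drosophila-like),
# written 5'->3' along the J strand; "-" marks N-strand genes; the control
# region sits between srRNA and trnI and acts as an adjacency barrier.
trnI+,trnQ-,trnM+,ND2+,trnW+,trnC-,trnY-,COI+,trnL2+,COII+,trnK+,trnD+,ATP8+,ATP6+,COIII+,trnG+,ND3+,trnA+,trnR+,trnN+,trnS1+,trnE+,trnF-,ND5-,trnH-,ND4-,ND4L-,trnT+,trnP-,ND6+,CYTB+,trnS2+,ND1-,trnL1-,lrRNA-,trnV-,srRNA-,CR
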