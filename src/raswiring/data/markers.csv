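subtype,marker
epithelial,EPCAM
epithelial,KRT8
epithelial,KRT18
epithelial,KRT19
epithelial,CDH1
muscle,DES
muscle,ACTA2
muscle,MYH2
muscle,TNNT2
muscle,MYOG
adipose,ADIPOQ
adipose,LEP
adipose,PLIN1
adipose,FABP4
adipose,CFD
neuronal,MAP2
neuronal,RBFOX3
neuronal,SYP
neuronal,TUBB3
neuronal,ENO2
connective,COL1A1
connective,COL1A2
connective,COL3A1
connective,VIM
connective,FN1
lymphoid,PTPRC
lymphoid,CD68
lymphoid,CD19
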