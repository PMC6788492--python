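assay_id,gene_symbol,gene_name,predicted_direction,functional_group,passed_efficiency
CA4,CA4,Carbonic anhydrase 4,up,ion regulation,True
CFTR-I,CFTR-I,Cystic fibrosis transmembrane conductance regulator I,up,ion regulation,True
NKAa1-b,NKAa1-b,Na+/K+-ATPase alpha-1b (seawater),up,ion regulation,True
NKCC,NKCC,Na+/K+/2Cl- co-transporter,up,ion regulation,False
HBA,HBA,Hemoglobin subunit alpha,up,oxygen transport,True
HBAt,HBAt,Hemoglobin subunit alpha (true HBA),up,oxygen transport,True
RHAG,RHAG,Rhesus blood group-associated glycoprotein,up,oxygen transport,True
MPC1,MPC1,Mitochondrial pyruvate carrier 1-like,up,metabolic rate,True
GAPDH,GAPDH,Glyceraldehyde-3-phosphate dehydrogenase,up,metabolic rate,False
NDUFB2,NDUFB2,NADH dehydrogenase 1 beta subcomplex subunit 2,up,metabolic rate,True
NDUFB4,NDUFB4,NADH dehydrogenase 1 beta subcomplex subunit 4,up,metabolic rate,True
RPL31,RPL31,60S ribosomal protein L31,up,growth,True
SLC16A10,SLC16A10,Monocarboxylate transporter 10-like,up,growth,True
EEF2,EEF2,Elongation factor 2,up,growth,True
CYP2K1,CYP2K1,Cytochrome P450 2K1,up,calcium uptake,True
S100A4,S100A4,Protein S100-A4,up,calcium uptake,False
WHRN,WHRN,Whirlin,up,structural integrity,False
ACTB,ACTB,Beta actin,up,structural integrity,True
TSPO,TSPO,Translocator protein,up,immunity,True
RGS5,RGS5,Regulation of G protein signalling 5,up,immunity,False
FKBP5,FKBP5,FK506-binding protein 5,up,immunity,True
CLEC4M,CLEC4M,C-type lectin domain family 4 member M,up,immunity,True
THRB1,THRB1,Thyroid hormone receptor beta 1,up,hormone,True
GHR1,GHR1,Growth hormone receptor 1,up,hormone,True
NR3C1,NR3C1,Glucocorticoid receptor 1,up,hormone,True
NKAa1-a,NKAa1-a,Na+/K+-ATPase alpha-1a (freshwater),down,ion regulation,True
GlyT2,GlyT2,Na- and Cl-dependent glycine transporter 2,down,ion regulation,False
CCL4,CCL4,C-C motif chemokine 4,down,immunity,True
CCL19,CCL19,C-C motif chemokine 19,down,immunity,True
IFI44,IFI44,Interferon-induced protein 44,down,immunity,True
MS4A4A,MS4A4A,Membrane-spanning 4-domains A-4A,down,immunity,True
PLK2,PLK2,Serine/threonine-protein kinase PLK2,down,immunity,True
CD3Z,CD3Z,T-cell surface glycoprotein CD3 zeta chain precursor,down,immunity,False
UBA1,UBA1,Ubiquitin-like modifier-activating enzyme 1 X,down,immunity,True
EXO1,EXO1,Exonuclease 1,down,immunity,True
NAMPT,NAMPT,Nicotinamide phosphoribosyltransferase,down,immunity,True
IL12B,IL12B,Interleukin-12 beta,down,immunity,True
MCM4,MCM4,DNA replication licensing factor MCM4-B,down,immunity,True
TUBA8L2,TUBA8L2,"Tubulin, alpha 8 like 2",down,immunity,True
FMNL1,FMNL1,Formin-like protein 1,down,immunity,True
TRA,TRA,T-cell receptor alpha,down,immunity,True
TYK2,TYK2,Non-receptor tyrosine-protein kinase,down,immunity,False
WAS,WAS,Wiskott-Aldrich Syndrome protein,down,immunity,True
RGS21,RGS21,Regulator of G-protein signalling 21,down,immunity,True
PRLR,PRLR,Prolactin receptor,down,hormone,True
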