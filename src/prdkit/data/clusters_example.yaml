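# Curated functional-cluster map: GO term or Pfam domain ID -> cluster label.
# This grouping is editable data, not computed; extend or replace it for
# your own annotation sets.
GTP_EFTU: nucleotide binding
Rho_RNA_bind: nucleotide binding
Rho_N: nucleotide binding
IF2: nucleotide binding
IF2_N: nucleotide binding
SSB: nucleotide binding
zinc_ribbon_2: nucleotide binding
HTH_25: nucleotide binding
S1: nucleotide binding
ATP-synt_ab: nucleotide binding
OB_RNB: nucleotide binding
LysM: cell wall dynamics
Glucosaminidase: cell wall dynamics
Glycos_transf_2: cell wall dynamics
Transpeptidase: cell wall dynamics
Transgly: cell wall dynamics
SLH: cell wall dynamics
PASTA: cell wall dynamics
CHAP: cell wall dynamics
Collagen: cell wall dynamics
NlpC_P60: cell wall dynamics
G5: cell wall dynamics
fn3: cell wall dynamics
CW_binding_1: cell wall dynamics
CBM_5_12: cell wall dynamics
DUF1388: cell wall dynamics
SPOR: invasion and virulence
GerA: invasion and virulence
Secretin: invasion and virulence
Secretin_N: invasion and virulence
PDZ: invasion and virulence
IcmL: invasion and virulence
Endotoxin_N: invasion and virulence
TPR_1: protein-protein interaction
TPR_2: protein-protein interaction
TPR_4: protein-protein interaction
Metallophos: iron transport
NEAT: iron transport
FecR: iron transport
Anti-sigma: heat-shock
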