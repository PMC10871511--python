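# Side-chain fragmentation mechanism definitions (default catalogue).
# One record per line: residues | label | kind | C,H,N,O,S,z
# 'CTERM' scopes a record to the C-terminal carboxyl. Reserved words:
# 'type' (backbone cleavage; forbidden in labels), 'charged' (kind of a
# non-relative detected-ion event), 'side' (marks a side-chain event;
# a residue-scoped relative label without it fires only alongside a
# C-terminal loss).
NQ | side ammonia loss | relative | 0,3,1,0,0,0
ST | side beta-elimination | relative | 0,2,0,1,0,0
C | side beta-elimination | relative | 0,2,0,0,1,0
DE | side carboxyl loss (whole) | relative | 1,1,0,2,0,0
DE | side carboxyl loss (partial radical) | relative | 0,1,0,1,0,0
DE | side carboxyl loss (partial) | relative | 0,2,0,1,0,0
M | side partial chain loss | relative | 2,5,0,0,1,0
K | side chain cyclization | relative | 0,3,1,0,0,0
R | side partial guanidino loss | relative | 1,2,2,0,0,0
R | side guanidino loss + alkene | relative | 1,6,3,0,0,0
IKP | alkene formation | relative | 0,1,0,0,0,0
C | side chain loss | relative | 1,3,0,0,1,0
D | side chain loss | relative | 2,3,0,2,0,0
E | side chain loss | relative | 3,5,0,2,0,0
F | side chain loss | relative | 7,7,0,0,0,0
H | side chain loss | relative | 4,5,2,0,0,0
I | side chain loss | relative | 4,9,0,0,0,0
K | side chain loss | relative | 4,10,1,0,0,0
L | side chain loss | relative | 4,9,0,0,0,0
M | side chain loss | relative | 3,7,0,0,1,0
N | side chain loss | relative | 2,4,1,1,0,0
Q | side chain loss | relative | 3,6,1,1,0,0
R | side chain loss | relative | 4,10,3,0,0,0
S | side chain loss | relative | 1,3,0,1,0,0
T | side chain loss | relative | 2,5,0,1,0,0
V | side chain loss | relative | 3,7,0,0,0,0
W | side chain loss | relative | 9,8,1,0,0,0
F | charged side chain loss | charged | 7,7,0,0,0,1
F | charged side chain loss (alkene) | charged | 8,7,0,0,0,1
Y | charged side chain loss | charged | 7,7,0,1,0,1
Y | charged side chain loss (alkene) | charged | 8,7,0,1,0,1
W | charged side chain loss | charged | 9,8,1,0,0,1
H | charged side chain loss | charged | 4,5,2,0,0,1
H | charged side chain loss (alkene) | charged | 5,5,2,0,0,1
H | charged side chain loss (radical) | charged | 4,6,2,0,0,1
M | charged side chain loss | charged | 3,7,0,0,1,1
M | charged side chain methylene sub frag loss | charged | 2,5,0,0,1,1
L | charged side chain loss | charged | 4,9,0,0,0,1
CTERM | carboxyl loss (whole) | relative | 1,1,0,2,0,0
CTERM | carboxyl loss (partial radical) | relative | 0,1,0,1,0,0
CTERM | carboxyl loss (partial) | relative | 0,2,0,1,0,0
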