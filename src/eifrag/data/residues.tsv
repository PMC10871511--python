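# code	name	side_chain_class	C	H	N	O	S  (free neutral amino acid)
G	Glycine	none	2	5	1	2	0
A	Alanine	aliphatic	3	7	1	2	0
S	Serine	alcohol	3	7	1	3	0
P	Proline	aliphatic	5	9	1	2	0
V	Valine	aliphatic	5	11	1	2	0
T	Threonine	alcohol	4	9	1	3	0
C	Cysteine	thiol	3	7	1	2	1
L	Leucine	aliphatic	6	13	1	2	0
I	Isoleucine	aliphatic	6	13	1	2	0
N	Asparagine	amide	4	8	2	3	0
D	Aspartate	acidic	4	7	1	4	0
Q	Glutamine	amide	5	10	2	3	0
K	Lysine	basic	6	14	2	2	0
E	Glutamate	acidic	5	9	1	4	0
M	Methionine	thioether	5	11	1	2	1
H	Histidine	aromatic	6	9	3	2	0
F	Phenylalanine	aromatic	9	11	1	2	0
R	Arginine	basic	6	14	4	2	0
Y	Tyrosine	aromatic	9	11	1	3	0
W	Tryptophan	aromatic	11	12	2	2	0
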