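# Nearest-neighbor stacking free energies dG at 37 C (310.15 K), kcal/mol.
# Watson-Crick stacks: unified parameters (SantaLucia 1998, PNAS 95:1460).
# Internal single mismatches: Allawi & SantaLucia 1997-1998 (Biochemistry
# 36:10581; 37:2170; 37:9435; NAR 26:2694) and Peyret et al. 1999
# (Biochemistry 38:3468); dG = dH - T*dS at 310.15 K.
# Key: stack of current base pair (cur_x template, cur_y copy) on the
# previously formed pair (prev_x, prev_y); template read 3'->5', copy 5'->3'.
# One orientation per measured stack; the strand-symmetric mirror is implied.
prev_x	prev_y	cur_x	cur_y	dG_kcal_mol
A	T	A	A	0.699065
A	T	A	C	1.33497
A	T	A	G	0.70489
A	T	C	A	0.9188
A	T	C	C	1.01354
A	T	C	T	0.782895
A	T	G	A	0.482895
A	T	G	G	0.48346
A	T	G	T	0.343795
A	T	T	A	-0.593805
A	T	T	C	0.982895
A	T	T	G	0.427255
A	T	T	T	0.665225
C	G	A	A	0.13947
C	G	A	C	0.47857
C	G	A	G	-0.49248
C	G	A	T	-1.45264
C	G	C	A	0.79587
C	G	C	C	0.839665
C	G	C	G	-1.828015
C	G	C	T	1.012975
C	G	G	A	-0.28985
C	G	G	C	-2.23234
C	G	G	G	-1.09963
C	G	G	T	-0.585155
C	G	T	A	-1.31467
C	G	T	C	0.62519
C	G	T	G	0.07444
C	G	T	T	0.40526
G	C	A	A	0.40263
G	C	A	C	0.78609
G	C	A	G	0.09398
G	C	A	T	-1.28685
G	C	C	A	0.752445
G	C	C	C	0.73308
G	C	C	G	-2.16392
G	C	C	T	0.391915
G	C	G	A	0.013345
G	C	G	G	-0.154705
G	C	G	T	-0.3188
G	C	T	A	-1.459595
G	C	T	C	0.595675
G	C	T	G	-0.471245
G	C	T	T	-0.09963
G	T	T	G	0.52293
T	A	A	A	0.672745
T	A	A	C	0.77181
T	A	A	G	0.013345
T	A	A	T	-0.87294
T	A	C	A	0.87331
T	A	C	C	1.36466
T	A	C	T	0.72293
T	A	G	A	0.113345
T	A	G	G	-0.153575
T	A	G	T	0.074245
T	A	T	A	-1.01467
T	A	T	C	0.63797
T	A	T	G	0.720865
T	A	T	T	0.64962
T	G	G	T	1.153575
T	G	T	G	0.744555
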