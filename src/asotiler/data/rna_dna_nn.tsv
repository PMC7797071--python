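# Nearest-neighbor thermodynamic parameters for RNA/DNA hybrid duplexes,
# Sugimoto et al. (1995) Biochemistry 34:11211-11216.
# Stacks are indexed by the RNA strand dinucleotide, 5'->3'; the DNA strand is
# the Watson-Crick complement. Units: delta_H kcal/mol, delta_S cal/(K*mol).
# dinucleotide	delta_H_kcal	delta_S_cal
AA	-7.8	-21.9
AC	-5.9	-12.3
AG	-9.1	-23.5
AU	-8.3	-23.9
CA	-9.0	-26.1
CC	-9.3	-23.2
CG	-16.3	-47.1
CU	-7.0	-19.7
GA	-5.5	-13.5
GC	-8.0	-17.1
GG	-12.8	-31.9
GU	-7.8	-21.6
UA	-7.8	-23.2
UC	-8.6	-22.9
UG	-10.4	-28.4
UU	-11.5	-36.4
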