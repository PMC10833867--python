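# Synthetic placeholder profile parameters for six common lipids.
# These are NOT production fit values: they are self-consistent
# piecewise parameters with qualitatively reasonable head-group and
# tail-length trends, shipped so the scorer runs out of the box.
# Replace this table with parameters fitted to your own bilayer
# charge-density grids (see fit-profile) for quantitative work.
lipid_name	A1	A2	A3	A4	C1	C2	C3	C4	C5	z_c	has_salt	reference_depth
DLPC	0.0	-2.0	17.0	2.0	0.00010775733049173262	0.0	-0.06228373702422146	0.0	10.0	17.0	False	40.0
DLPE	0.0	-2.9999999999999964	16.5	1.8	0.0001551536738113247	0.0	-0.08448117539026631	0.0	13.0	16.5	False	40.0
DLPG	0.0	-1.2000000000000028	17.5	2.2	5.757600999583507e-05	0.0	-0.03526530612244898	0.0	6.0	17.5	True	40.0
DPPC	0.0	-2.0	19.0	2.0	7.289692374981776e-05	0.0	-0.05263157894736842	0.0	10.5	19.0	False	40.0
DOPC	0.0	-1.8000000000000007	18.5	2.1	7.341951945430515e-05	0.0	-0.05025566106647188	0.0	9.5	18.5	False	40.0
POPC	0.0	-1.8000000000000007	18.5	2.1	7.598066548178092e-05	0.0	-0.05200876552227904	0.0	9.8	18.5	False	40.0
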