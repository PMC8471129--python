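# Ancestral insect mitochondrial gene order (pancrustacean ground pattern),
# starting from trnI by convention. strand: J = majority, N = minority.
# default_length_bp: typical phasmatodean gene sizes used by the synthetic
# generator (13 PCGs sum to 11,178 bp; 22 tRNAs to 1,454 bp; rRNAs to 2,070 bp).
# Editable: the generator and the order comparison read this at import time.
name	strand	kind	default_length_bp
trnI	J	tRNA	66
trnQ	N	tRNA	68
trnM	J	tRNA	68
ND2	J	PCG	1020
trnW	J	tRNA	67
trnC	N	tRNA	64
trnY	N	tRNA	65
COX1	J	PCG	1536
trnL2	J	tRNA	66
COX2	J	PCG	684
trnK	J	tRNA	70
trnD	J	tRNA	66
ATP8	J	PCG	159
ATP6	J	PCG	675
COX3	J	PCG	789
trnG	J	tRNA	65
ND3	J	PCG	354
trnA	J	tRNA	65
trnR	J	tRNA	64
trnN	J	tRNA	65
trnS1	J	tRNA	66
trnE	J	tRNA	65
trnF	N	tRNA	66
ND5	N	PCG	1719
trnH	N	tRNA	65
ND4	N	PCG	1344
ND4L	N	PCG	294
trnT	J	tRNA	64
trnP	N	tRNA	65
ND6	J	PCG	525
CYTB	J	PCG	1137
trnS2	J	tRNA	67
ND1	N	PCG	942
trnL1	N	tRNA	66
rrnL	N	rRNA	1285
trnV	N	tRNA	71
rrnS	N	rRNA	785
CR	J	CR	2200
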