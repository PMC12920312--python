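kind	p1	p2	p3	from	to
DOUBLE					
DOUBLE					
DOUBLE					
DELETE	15	16			
DELETE	28	30			
MUTATE	8			G	C
MUTATE	10			D	S
MUTATE	11			S	C
MUTATE	14			D	C
MUTATE	16			D	S
MUTATE	18			G	C
MUTATE	19			A	P
MUTATE	20			D	V
MUTATE	22			G	A
MUTATE	24			D	S
MUTATE	25			S	Q
DOUBLE					
SEGDUP	27	27	27		
MUTATE	2			D	Y
MUTATE	3			S	K
MUTATE	4			G	I
MUTATE	9			A	V
MUTATE	17			S	E
MUTATE	21			S	N
MUTATE	23			A	I
MUTATE	27			A	D
MUTATE	28			A	S
MUTATE	29			A	I
MUTATE	30			D	F
MUTATE	31			S	V
MUTATE	32			G	I
MUTATE	33			A	D
MUTATE	34			D	A
MUTATE	35			S	D
MUTATE	36			C	T
MUTATE	37			A	C
MUTATE	38			S	I
MUTATE	39			C	D
MUTATE	40			G	C
MUTATE	41			A	G
MUTATE	42			C	N
MUTATE	43			A	C
MUTATE	44			S	A
MUTATE	45			S	N
MUTATE	46			C	V
MUTATE	47			P	C
MUTATE	48			V	P
MUTATE	49			S	V
MUTATE	50			A	G
MUTATE	52			S	P
MUTATE	53			Q	V
MUTATE	54			G	Q
MUTATE	55			A	E
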