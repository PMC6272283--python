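c1ccccc1NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 4a
c1ccccc1CNC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 4b
Clc1ccc(cc1)NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 4c
Brc1ccc(cc1)NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 4d
COc1ccc(cc1)NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 4e
Cc1ccc(cc1)NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 4f
COc1ccccc1NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 4g
Cc1ccccc1NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 4h
c1ccc2ccccc2c1NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 4i
Fc1ccc(cc1)NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 4j
Clc1cccc(c1)NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 4k
C1CCCCC1NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 4l
c1ccccc1NC(=O)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 5a
Fc1ccc(cc1)NC(=O)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 5b
Clc1ccc(cc1)NC(=O)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 5c
Brc1ccc(cc1)NC(=O)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 5d
COc1ccc(cc1)NC(=O)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 5e
Cc1ccc(cc1)NC(=O)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 5f
COc1ccccc1NC(=O)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 5g
Brc1cccc(c1)NC(=O)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 5h
Fc1ccccc1NC(=O)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 5i
Clc1cccc(c1)NC(=O)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 5j
c1ccc2ccccc2c1NC(=O)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 5k
Clc1ccccc1NC(=O)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 5l
c1ccccc1C(=O)NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 6a
Cc1ccc(cc1)C(=O)NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 6b
Clc1ccc(cc1)C(=O)NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 6c
c1ccc2cc(ccc2c1)C(=O)NC(=S)N/N=C/C1=C2CN3C(=CC4=C(C3=O)COC(=O)[C@@]4(CC)O)C2=NC2=CC=CC=C12 6d
CC[C@@]1(C2=C(COC1=O)C(=O)N3CC4=CC5=CC=CC=C5N=C4C3=C2)O 1
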