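>pGL3-167|sense
ccaagcttccttcgcgccctgggccatct
>pGL3-167|antisense
ccccatggctcctcggcgactccttcct
>pGL3-840|sense
ccaagcttccttcgcgccctgggccatct
>pGL3-840|antisense
ccccatggcgagagcgcgaacagggctggtg
>pGL3-77/105A|sense
ccaagcttccttcgcgccctgggccatctccctcccacctccctccgcggagcagccaga
cagcgagggccccggccgggggcaAAAAAAAAAAAAAAAAAAAAAAAA
>pGL3-77/105A|antisense
ccccatgggctcctcggcgactccttcctccgctccgggccgaggccggccccgcgggcg
gctcagagccgTTTTTTTTTTTTTTTTTTTTTTTTTTTTTtgcccccg
>pGL3-92/105A|sense
ccaagcttccttcgcgccctgggccatctccctcccacctccctccgcggagcagccaga
cagcgagggccccggccgggggcaggggggacgccccgtAAAAAAAAA
>pGL3-92/105A|antisense
ccccatgggctcctcggcgactccttcctccgctccgggccgaggccggccccgcgggcg
gctcagagccgTTTTTTTTTTTTTTacggggcgtcccccctgcccccg
>pGL3-92/98A|sense
ccaagcttccttcgcgccctgggccatctccctcccacctccctccgcggagcagccaga
cagcgagggccccggccgggggcaggggggacgccccgtAAAAAAAAc
>pGL3-92/98A|antisense
ccccatgggctcctcggcgactccttcctccgctccgggccgaggccggccccgcgggcg
gctcagagccgggggggTTTTTTTTacggggcgtcccccctgcccccg
>pGL3-99/105A|sense
ccaagcttccttcgcgccctgggccatctccctcccacctccctccgcggagcagccaga
cagcgagggccccggccgggggcaggggggacgccccgtccggggcaa
>pGL3-99/105A|antisense
ccccatgggctcctcggcgactccttcctccgctccgggccgaggccggccccgcgggcg
gctcagagccgTTTTTTTgccccggacggggcgtcccccctgcccccg
>pGL3-50/56A|sense
ccaagcttccttcgcgccctgggccatctccctcccacctccctccgcggagcagccAAA
AAAAgagggccccggccgggggcaggggggacgccccgtccggggcac
>pGL3-50/56A|antisense
ccccatgggctcctcggcgactccttcctccgctccgggccgaggccggccccgcgggcg
gctcagagccgggggggtgccccggacggggcgtcccccctgcccccg
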