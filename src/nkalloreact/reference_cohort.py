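"""Published marginal distributions of the two transplant cohorts this
pipeline emulates (43 genoidentical and 35 haploidentical donor/recipient
pairs).

Only donor-level marginal counts are available — the underlying genotypes
are not — so these tables serve two internal-consistency checks rather
than a reanalysis: the neutral/better/best B-content categorisation must
be reproducible from the B-pattern and Cen-B marginals alone, and the
receptor-ligand quantitative synthesis must be the count of its four
binary component models.
"""

#: donors per B-pattern value (number of B motifs, 0-4)
GENOIDENTICAL_B_PATTERN = {0: 11, 1: 18, 2: 9, 3: 4, 4: 1}
HAPLOIDENTICAL_B_PATTERN = {0: 11, 1: 12, 2: 8, 3: 3, 4: 1}

#: donors per Cen-B motif count (0-2)
GENOIDENTICAL_CEN_B = {0: 17, 1: 19, 2: 7}
HAPLOIDENTICAL_CEN_B = {0: 14, 1: 13, 2: 8}

#: donors per B-content category as published
GENOIDENTICAL_B_CONTENT = {"neutral": 29, "better": 7, "best": 7}
HAPLOIDENTICAL_B_CONTENT = {"neutral": 23, "better": 4, "best": 8}

#: pairs predicted alloreactive ("yes") per receptor-ligand model
GENOIDENTICAL_RL_YES = {"2DL1-C2": 8, "3DL1-Bw4": 14, "3DL2-A3/11": 23, "2DL2/3-C1": 5}
HAPLOIDENTICAL_RL_YES = {"2DL1-C2": 14, "3DL1-Bw4": 5, "3DL2-A3/11": 19, "2DL2/3-C1": 6}

#: pairs per value of the receptor-ligand quantitative synthesis (0-4)
GENOIDENTICAL_RL_QUANT = {0: 8, 1: 20, 2: 15, 3: 0}
HAPLOIDENTICAL_RL_QUANT = {0: 6, 1: 17, 2: 9, 3: 3}
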