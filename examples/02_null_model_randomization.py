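"""Null models I and II: profile-preserving MSA randomization.

Null model I permutes every column independently, destroying all
inter-sequence structure.  Null model II starts from a null-I sample and
anneals within-column swaps until the randomized alignment's pairwise
Hamming-distance matrix matches the input's — preserving both the
conservation profile and the phylogenetic distance structure.
"""

import numpy as np

import phylonull as pn

sample = pn.generate_phylo_msa(pn.BenchmarkSpec(M=100, L=40, seed=3))
aln = sample.alignment
d0 = pn.hamming_matrix(aln)
iu = np.triu_indices(aln.M, k=1)


def corr_to_input(randomized):
    return np.corrcoef(pn.hamming_matrix(randomized).d[iu], d0.d[iu])[0, 1]


null1 = pn.null_model_I(aln, seed=1)
print(f"null model I : distance-matrix correlation to input r = {corr_to_input(null1):.3f}")

null2, state = pn.null_model_II(aln, pn.AnnealSchedule(seed=1))
last = state.trace[-1]
print(f"null model II: r = {last['pearson']:.3f} after {last['sweep']} sweeps "
      f"(objective {state.trace[0]['objective']:.2f} -> {last['objective']:.2f})")
# Null I decorrelates the distances (r ~ 0); null II recovers them
# (r >= 0.97) while both preserve every column's symbol counts exactly.
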