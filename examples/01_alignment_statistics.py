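"""Column statistics, covariance spectrum and distance matrix of an MSA.

Generates a small tree-evolved synthetic family, then computes the
summary statistics every other analysis consumes: site frequencies,
pair frequencies, the (L*q x L*q) covariance matrix and its eigenvalue
spectrum, and the matrix of pairwise Hamming distances.
"""

import numpy as np

import phylonull as pn

sample = pn.generate_phylo_msa(pn.BenchmarkSpec(M=80, L=40, seed=0))
aln = sample.alignment
print(f"alignment: M={aln.M} sequences x L={aln.L} columns, q={aln.q} symbols")

profile = pn.compute_profile(aln)
print(f"most conserved column: {profile.freq.max(axis=1).argmax()} "
      f"(top symbol frequency {profile.freq.max():.2f})")

C = pn.covariance_matrix(profile, pn.compute_pair_frequencies(aln))
spectrum = pn.eigen_spectrum(C)
print(f"largest eigenvalue of C: {spectrum.eigenvalues[0]:.3f}; "
      f"fraction of eigenvalues > 0.1: {spectrum.cumulative(0.1):.3f}")

dist = pn.hamming_matrix(aln)
print(f"mean pairwise Hamming distance: {dist.upper().mean():.3f} "
      "(fraction of differing columns, gap = 21st symbol)")
# A fat tail of large eigenvalues and structured distances are the
# signature of shared phylogenetic history in the alignment.
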