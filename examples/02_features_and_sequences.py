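"""Clean, compress and window per-pen features into labelled sequences.

The transform drops zero-variance columns, projects onto the first
principal components and min-max scales to [0, 1]; windows of 10
consecutive frames become the classifier inputs, labelled positive when
any member frame shows biting.
"""

import numpy as np

from pentail.pipeline import prepare_features
from pentail.sequences import build_sequences, to_sequence_image
from pentail.synthetic import SynthConfig, generate

table, raw, _ = generate(SynthConfig(n_pens=6, frames_per_pen=1500,
                                     n_features=128, signature_dim=16, seed=42))

transform, transformed = prepare_features(table, raw, n_pc=16)
print(f"raw width {transform.n_raw} -> retained "
      f"{int(transform.variance_mask.sum())} -> {transform.output_dim} PCs")
evr = transform.explained_variance / transform.explained_variance.sum()
print(f"explained variance of PC1..3: {np.round(evr[:3], 3)}")

seqs = build_sequences(table, transformed, n_obs=10)
print(f"{len(seqs)} windows of {seqs.n_obs} frames, "
      f"{seqs.n_positive} positive ({100 * seqs.n_positive / len(seqs):.1f}%)")
img = to_sequence_image(seqs.x[0])
print(f"sequence-image shape for the CNN branch: {img.shape}")
# Values are already in [0, 1]; the CNN convolves this 10 x 16 grid
# directly, with no resizing.
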