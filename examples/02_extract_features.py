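"""Build the 93-dimensional descriptor matrix for a small benchmark.

Each sequence becomes 75 gapped-dipeptide frequencies (5x5 reduced
alphabet x gaps 0, 1, 2) plus 18 auto-cross covariance values (3
physicochemical properties, lags 1-2), a fixed-length vector regardless
of sequence length.
"""

from raacdip import GeneratorConfig, extract_feature_matrix, generate

dataset = generate(GeneratorConfig(n_pos=15, n_neg=15, seed=42))
matrix = extract_feature_matrix(dataset.records)

print(f"samples x features: {matrix.n_samples} x {matrix.n_features}")
print(f"first 5 columns  : {matrix.feature_names[:5]}")
print(f"columns 74-78    : {matrix.feature_names[73:78]}  (dipeptides end, ACC begins)")
row = matrix.data.iloc[0]
print(f"{matrix.sample_ids[0]}: F*C freq = {row['F*C']:.4f}, "
      f"AC.hydrophobicity.lag1 = {row['AC.hydrophobicity.lag1']:.4f}")
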