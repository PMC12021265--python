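"""Featurize a cohort: pooled embeddings + classical encoders + codon
statistics + gene context, as one samples x features table."""

import nifcast as nc
from nifcast.synthetic import SyntheticConfig, generate_strains

records, _ = generate_strains(SyntheticConfig(n_strains=20, seed=3))
X = nc.build_feature_table(records)
emb, aux = nc.split_blocks(X)

print(f"feature table     : {X.shape[0]} strains x {X.shape[1]} features")
print(f"embedding block   : {emb.shape[1]} columns (emb_0001..emb_1024)")
print(f"auxiliary block   : {aux.shape[1]} columns")
print()
cols = ["paac_A", "Average_nifD_E", "Average_nifD_CAI", "ECD",
        "dist_nifD_nifK", "copy_nifH"]
print(X[cols].head(5).round(3).to_string())
# paac_A is the Ala share of the pseudo-composition; Average_nifD_E the
# mean within-family codon-usage deviation of nifD copies (expression
# proxy); ECD the genome-wide codon-bias strength; dist the bp gap
# between the closest nifD/nifK copies.
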