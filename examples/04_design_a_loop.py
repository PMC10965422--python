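"""Design a masked loop: predicted coordinates plus sampled sequences.

Trains briefly on toy complexes, then masks the loop of a held-out
complex and designs it: one forward pass gives loop Cα coordinates and
a 20-way amino-acid distribution per position, from which candidate
sequences are sampled. The designed chain is assembled back into a
Cα-level complex ready for external full-atom tools.
"""

import numpy as np

from cdrdesign import (
    Model,
    ModelConfig,
    TrainConfig,
    ToySpec,
    design_cdr,
    assemble_design_chain,
    encode_sample,
    select_context,
    train,
)
from cdrdesign.cdr_schemes import cdr_sequence
from cdrdesign.synthetic import make_toy_complex
from cdrdesign.train_eval import rmsd_metric

spec = ToySpec(n_complexes=160, seed=11)
samples = []
for i in range(160):
    rec, cdr, _ = make_toy_complex(spec, i)
    samples.append(encode_sample(select_context(rec, "H"), cdr, k_neighbors=24))

model = Model(ModelConfig(n_layers=5, hidden_dim=48, aa_embed_dim=32,
                          k_neighbors=24), seed=11)
train(samples, model, TrainConfig(learning_rate=2e-3, max_steps=2000, seed=11))

target, cdr, _ = make_toy_complex(spec, 500)  # index outside the training set
native = cdr_sequence(target.chain("H"), cdr)
result = design_cdr(model, target, cdr, n_samples=5, seed=42)

print(f"native loop:        {native}")
ml = design_cdr(model, target, cdr, n_samples=1, seed=0, temperature=0.0)
print(f"max-likelihood:     {ml.sampled_sequences[0]}")
for i, s in enumerate(result.sampled_sequences):
    print(f"sample {i}:           {s}")

sample = encode_sample(select_context(target, "H"), cdr, k_neighbors=24)
pred_rmsd = rmsd_metric(
    np.vstack([sample.truth_coords[: cdr.start_idx], result.cdr_coords,
               sample.truth_coords[cdr.end_idx + 1:]]),
    sample.truth_coords, sample.mask)
print(f"designed loop RMSD vs truth: {pred_rmsd:.3f} Å")

assembled = assemble_design_chain(target, result, sample_index=0)
print(f"assembled complex: "
      + ", ".join(f"{c.chain_id}({len(c)} aa)" for c in assembled.chains))
# Sampled sequences cluster around the native loop when the model has
# learned the flank-to-class code; disagreements show positions where
# the predicted distribution keeps real alternatives.
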