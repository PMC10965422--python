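"""The desk-scale loop-recovery experiment.

A compact end-to-end check that the model class, the masking scheme and
the local-loss training loop actually learn: toy complexes whose loop
geometry and sequence are a deterministic function of flanking residues
are generated, a small stack is trained for a few thousand steps, and
held-out recovery is measured against chance (5% per residue) and
against the straight-line anchor initialisation RMSD.

The protocol is fixed: 240 complexes (200 train / 40 held out), a
5-layer, 48-wide model on a 24-nearest-neighbour graph, 2000 Adam steps
at learning rate 2e-3. Five layers is the smallest stack the loss suite
admits (the structural-violation terms attach after layer 4); the
learning rate is raised from the full-scale default because a
desk-scale run has a far smaller step budget.
"""

from __future__ import annotations

from dataclasses import dataclass

from .egnn import Model, ModelConfig
from .graph_prep import encode_sample, select_context
from .synthetic import ToySpec, make_toy_dataset
from .train_eval import (
    TrainConfig,
    evaluate,
    straight_line_baseline_rmsd,
    train,
)

__all__ = ["RecoveryResult", "run_recovery_experiment"]

N_COMPLEXES = 240
N_TRAIN = 200
K_NEIGHBORS = 24
MODEL_KWARGS = dict(n_layers=5, hidden_dim=48, aa_embed_dim=32, k_neighbors=K_NEIGHBORS)
TRAIN_KWARGS = dict(learning_rate=2e-3, max_steps=2000, val_every=1000)


@dataclass
class RecoveryResult:
    top1_aar: float          # %, held-out, pooled over CDR residues
    top3_aar: float          # %
    rmsd: float              # Å, held-out mean CDR RMSD
    baseline_rmsd: float     # Å, straight-line anchor initialisation
    n_train: int
    n_test: int
    history: dict


def run_recovery_experiment(seed: int = 11, max_steps: int | None = None) -> RecoveryResult:
    """Generate data, train, and measure held-out recovery. Seeded, ~3–5 min."""
    spec = ToySpec(n_complexes=N_COMPLEXES, seed=seed)
    records, cdrs, _, _ = make_toy_dataset(spec)
    samples = []
    for rec, cdr in zip(records, cdrs):
        ctx = select_context(rec, "H")
        samples.append((encode_sample(ctx, cdr, k_neighbors=K_NEIGHBORS), "HCDR3"))
    train_set, test_set = samples[:N_TRAIN], samples[N_TRAIN:]

    model = Model(ModelConfig(**MODEL_KWARGS), seed=seed)
    kwargs = dict(TRAIN_KWARGS)
    if max_steps is not None:
        kwargs["max_steps"] = max_steps
    history = train(train_set, model, TrainConfig(seed=seed, **kwargs),
                    val_dataset=test_set[:10])
    report = evaluate(model, test_set)
    return RecoveryResult(
        top1_aar=report.top1_aar["HCDR3"],
        top3_aar=report.top3_aar["HCDR3"],
        rmsd=report.rmsd["HCDR3"],
        baseline_rmsd=straight_line_baseline_rmsd([s for s, _ in test_set]),
        n_train=len(train_set),
        n_test=len(test_set),
        history={"steps": len(history["steps"]), "val": history["val"]},
    )
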