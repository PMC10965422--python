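"""Train a small model on synthetic complexes and measure recovery.

Runs the desk-scale recovery experiment: 240 toy complexes whose loop
class is encoded in the flanking residues, a 5-layer equivariant stack,
2000 local-loss Adam steps. Reports held-out amino-acid recovery (AAR)
and loop RMSD against the straight-line initialisation baseline.
Takes a few minutes on one CPU. Pass --quick for a 400-step smoke run.
"""

import sys

from cdrdesign.experiments import run_recovery_experiment

quick = "--quick" in sys.argv
result = run_recovery_experiment(seed=11, max_steps=400 if quick else None)

print(f"train/test complexes: {result.n_train}/{result.n_test}")
print(f"held-out Top-1 AAR: {result.top1_aar:.1f}%  (chance: 5%)")
print(f"held-out Top-3 AAR: {result.top3_aar:.1f}%")
print(f"held-out loop RMSD: {result.rmsd:.3f} Å")
print(f"straight-line baseline RMSD: {result.baseline_rmsd:.3f} Å")
print("validation trajectory:")
for v in result.history["val"]:
    print(f"  step {v['step']:5d}: top1 {v['top1_aar']:5.1f}%  "
          f"rmsd {v['rmsd']:.3f} Å")
# Top-1 AAR far above 5% chance and RMSD below the baseline mean the
# network reads the flanking sequence code and rebuilds both the loop's
# sequence and its curved geometry from the masked straight line.
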