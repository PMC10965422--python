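"""Flexible-anchor CDR augmentation on a single heavy chain.

Builds a small chain whose loop residues spell EAYGMDV, locates the
loop by its numbering range, and enumerates every anchor-shifted
variant within ±k. Each variant is the same physical loop with its
boundary redrawn — the augmentation that exposes a design model to many
boundary conventions at once.
"""

import numpy as np

from cdrdesign import augment_anchors, cdr_sequence, locate_cdr
from cdrdesign.cdr_schemes import CdrDefinitionTable
from cdrdesign.structure_io import ChainRecord, ResidueRecord

seq = "QVQLVESGGG" + "EAYGMDV" + "WGQGTLVTVS"
chain = ChainRecord("H", "heavy", [
    ResidueRecord("H", 90 + i, "", aa, np.array([3.8 * i, 0.0, 0.0]))
    for i, aa in enumerate(seq)
])
table = CdrDefinitionTable("chothia", {"HCDR3": (100, 106)})

base = locate_cdr(chain, "HCDR3", table=table)
print(f"native loop: {cdr_sequence(chain, base)} "
      f"(rows {base.start_idx}..{base.end_idx})")

for k in (0, 1, 3):
    variants = augment_anchors(base, k=k, chain_len=len(chain))
    print(f"k={k}: {len(variants)} variants (max (2k+1)^2 = {(2*k+1)**2})")

print("\nsome k=1 variants (shift -> sequence):")
for v in augment_anchors(base, 1, len(chain)):
    print(f"  {v.shift} -> {cdr_sequence(chain, v)}")
# Interior loops give the full (2k+1)^2 grid; each line above is the
# same loop with one or both anchors moved by at most one residue.
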