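# Methods

## Data model

A complex is a list of chains with roles (heavy / light / antigen),
each chain an ordered list of residues carrying the author residue
number, insertion code, amino-acid type and one Cα coordinate. The
0-based position in the chain's residue list is the universal
coordinate used by every module; author numbering and insertion codes
are retained only to locate CDRs and to report results. Only `ATOM`
records with atom name `CA` are read (first altloc kept); non-canonical
residues map to an UNKNOWN symbol, which disqualifies a window from
being designable. Chain roles always come from an explicit mapping or a
tab-separated manifest, never from sequence inference.

## CDR location and flexible-anchor augmentation

CDRs are located by author-numbering ranges under a scheme table.
Shipped defaults: Chothia H1 26–32, H2 52–56, H3 95–102, L1 24–34,
L2 50–56, L3 89–97, with IMGT analogues; any table can be supplied as
YAML, since published range conventions differ at the margins.
Augmentation enumerates all shift pairs (δs, δe) ∈ [−k, k]², keeping a
variant iff its window is non-empty and both shifted anchors exist on
the chain, so an interior CDR yields exactly (2k+1)² variants and
clamping near termini only ever removes variants. k defaults to 5.
Variants overlapping a neighbouring CDR are not excluded — only the
chain-bounds rule applies.

Holding out a test set supports two levels of strictness: exact CDR
sequence identity, and a global-alignment identity threshold (default
reading of "similar": Needleman–Wunsch matches / aligned columns,
computed with Biopython's PairwiseAligner; pairs at or above the
threshold are dropped). The metric is parameterised because any
similarity cutoff is a convention.

## Graph encoding

One sample = one (complex, CDR) pair. Context selection keeps the
design chain whole, the partner antibody chain whole (if paired), and
antigen residues whose minimum Cα distance to the design chain is
≤ 16 Å (boundary inclusive; the convention is documented and tested).
Rows are concatenated design chain first, then partner, then antigen.
Loop coordinates are initialised at fractions i/(n+1) along the
anchor-to-anchor segment — the anchors are real residues, so the n
masked points are strictly interior; with coincident anchors all
points degenerate to that anchor. Loop tokens become MASK (id 20).
Edges are directed source→target pairs from each node's k nearest
others (Euclidean, ties to the lower index, deterministic), built once
on the masked input coordinates and held fixed across layers; rebuild
per layer is not implemented because fixed topology is the simpler
reading and the effect at these graph sizes is negligible. A config
switch would be the natural extension point.

## Network

Sixteen equivariant layers by default (`ModelConfig.n_layers`), each:

* messages m_ij = φ_e(f_i, f_j, g(‖x_i−x_j‖²)) over in-edges, with
  g(d²) = log(1 + d²/100) — an invariant, log-compressed distance
  feature. Raw squared distances (10³–10⁴ Ų on Å-scale complexes)
  saturate the MLPs and overflow across a deep stack; the compression
  is a numerical choice, not a modelling one.
* coordinate update x_i ← x_i + mean_j [ (x_i−x_j)/(‖x_i−x_j‖+1) · φ_x(m_ij) ],
  equivariant because only relative vectors scaled by invariant scalars
  enter; the /(d+1) normalisation bounds the step size.
* feature update f_i ← f_i + φ_h(f_i, mean_j m_ij) with the residual
  connection that the local-loss scheme complements.

After every layer the coordinate mask restores non-CDR rows to the
input coordinates exactly (an elementwise select, so the pinning is
bit-exact, which the tests assert). The 258-wide input embedding is
linearly projected to `hidden_dim` (default 256) before layer 1. A
two-layer feedforward head with SiLU in between maps final features to
20 logits. All arithmetic is float64 by default: at desk scale the
cost is negligible on CPU and it removes a train/test precision split;
`ModelConfig.dtype` exposes float32 for larger runs.

At least 5 layers are required, because the structural-violation
losses average over layers 5..N and their 1/(N−4) normalisation is
undefined below that.

## Losses

* RMSD term: mean over **all** layers of the loop-restricted RMSD in
  the fixed complex frame. No superposition is applied — the mask pins
  every non-CDR atom, so predicted and true frames coincide by
  construction.
* Repulsion: mean over layers 5..N of
  (1/(N_CDR·N_nonCDR)) Σ max(τ − d_ij, 0) over CDR×non-CDR pairs,
  τ = 4.2 Å.
* Neighbour distance: mean over layers 5..N of
  (1/(N_CDR+1)) Σ |d_pred − d_true| over the N_CDR+1 consecutive edges
  of the anchor→loop→anchor path. The denominator equals the edge
  count only when both anchor-adjacent edges are included, which fixes
  the interpretation.
* Cross-entropy with label smoothing 0.1: non-CDR rows averaged over
  all layers, CDR rows over the last four layers (sequence identity is
  supervised only once the structure has largely formed). The
  per-layer features are each passed through the shared head.
* Total: `10·(RMSD + repulsion + neighbour) + (CE_CDR + CE_nonCDR)`.
  The compositional identities are asserted exactly in the tests.

Every structural loss is validated against pure-loop oracles to 1e-6
and is invariant under joint rigid motion of prediction and truth.

## Training and evaluation

One sample per step (lengths vary; no padding), Adam, gradient clipping
off by default. The full-scale default learning rate is 1e-6; the
desk-scale experiments use 2e-3 because a few-thousand-step budget
needs correspondingly larger steps. Attaching losses to every layer
(local loss) keeps all layers' gradients alive in the deep stack — the
tests assert nonzero gradient at every layer. Validation runs
periodically; the checkpoint criterion is Top-1 AAR with RMSD as the
tie-break (both are logged, since "validation accuracy" admits either
reading). Runs are bit-reproducible given the seed.

Metrics: CDR Cα RMSD (fixed frame); Top-k AAR = percentage of loop
positions whose true type is among the k most probable, ties broken
toward the lower amino-acid index, pooled across residues
(micro-average) rather than averaged per sample.

## Design

Inference is one forward pass; loop coordinates come from the last
layer, per-position distributions from softmax of the head logits with
optional temperature (default 1.0, a convention; temperature 0 is the
argmax/maximum-likelihood mode). Positions are sampled independently —
the head defines per-residue marginals, not a joint autoregressive
model. Assembly replaces only the loop rows of the design chain and
merges the binding context within 16 Å. Full-atom reconstruction and
relaxation (PDBFixer / OpenMM class tools) sit behind an adapter that
returns the Cα-level PDB when no backend is installed and raises a
capability error — never a crash — when one is requested but absent.
Pipelines that estimate binding energies typically relax several times
and keep the best-scoring structure; that policy belongs to the
backend side of the adapter contract.

## Synthetic complexes

The generator emulates the one regularity the model must exploit:
loops fall into a small number of canonical conformations predictable
from their context. Each complex has an idealised design chain with
exact 3.8 Å Cα virtual bonds; the loop window's geometry (a planar arc
of class-specific curvature and bulge plane) and sequence are drawn
from one of 6 fixed classes; the single framework residue on each side
of the loop carries the class-identifying amino acid. An antigen chain
sits beyond the loop tip inside the 16 Å context but never closer than
3 Å to the antibody; an 8-residue partner chain is included; the whole
complex gets a random rigid motion and Gaussian coordinate noise
(σ = 0.1 Å, small enough that class membership stays unambiguous).

What passing on this data shows: the architecture can carry sequence
information from context into a masked loop and can move loop
coordinates from the straight-line initialisation to a class-specific
curved shape. What it does not show: performance on real
immunoglobulin statistics — real CDRs have no deterministic
flank-to-loop code, side-chain-mediated contacts, loop-length
diversity beyond the toy range, or crystallographic noise structure.

## The recovery experiment

`cdrdesign.experiments.run_recovery_experiment`: 240 complexes
(200 train / 40 held out), 5 layers × 48 hidden on a 24-nearest-
neighbour graph, 2000 steps at 2e-3 — the smallest stack the loss
suite admits, with a problem size chosen to finish in minutes on one
CPU. Success criteria: held-out Top-1 AAR above 60% (chance 5%) and
loop RMSD below the straight-line baseline. A representative run
(seed 11) reaches 71.5% / 98.6% Top-1/Top-3 and 0.334 Å vs a 1.836 Å
baseline.

## Known limitations

* Cα-only; no frames, side chains or full-atom geometry in the core.
* Single deterministic structure prediction per complex; diversity
  comes only from sequence sampling.
* Loop length is fixed by the chosen CDR window at inference (design
  with a different length requires supplying a shifted window).
* No automatic numbering assignment (ANARCI-style); author numbering
  must already follow the chosen scheme.
* The graph is built once from the masked initialisation; extremely
  long loops could in principle move outside their initial
  neighbourhood structure.
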