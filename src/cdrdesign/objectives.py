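"""Training losses: layer-wise RMSD, structural-violation hinges, and
label-smoothed cross-entropy on the amino-acid head.

Layer-range semantics:

* the RMSD term and the non-CDR cross-entropy average over **all** layers;
* the repulsion and neighbour-distance violations average over layers
  5..N (they attach only once a reasonable structure has formed);
* the CDR cross-entropy averages over the **last four** layers.

The total is ``10·(RMSD + repulsion + neighbour) + (CE_cdr + CE_noncdr)``;
the 10× weight pushes the model to learn structure first. All structural
terms are computed in the fixed complex frame with no superposition —
the coordinate mask pins every non-CDR atom, so predicted and true
frames coincide by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concatenate, tensor
from .egnn import ForwardTrace, Model

__all__ = [
    "TAU_REPULSION",
    "LABEL_SMOOTHING",
    "STRUCTURE_WEIGHT",
    "VIOLATION_SKIP_LAYERS",
    "CE_CDR_LAYERS",
    "LossBreakdown",
    "rmsd_loss",
    "repulsion_loss",
    "neighbor_loss",
    "ce_noncdr_loss",
    "ce_cdr_loss",
    "compute_losses",
    "total_loss",
]

#: clash threshold τ between CDR and non-CDR Cα atoms, Å
TAU_REPULSION = 4.2

#: label-smoothing weight for both cross-entropy terms
LABEL_SMOOTHING = 0.1

#: weight of the structural loss in the total
STRUCTURE_WEIGHT = 10.0

#: violation losses attach after this many layers
VIOLATION_SKIP_LAYERS = 4

#: CDR cross-entropy uses this many final layers
CE_CDR_LAYERS = 4


class UndefinedLossError(ValueError):
    """A loss was requested on a sample where it is undefined (empty mask)."""


@dataclass
class LossBreakdown:
    l_rmsd: float
    l_repulsion: float
    l_neighbor: float
    l_ce_cdr: float
    l_ce_noncdr: float

    @property
    def l_structure(self) -> float:
        return self.l_rmsd + self.l_repulsion + self.l_neighbor

    @property
    def l_ce_total(self) -> float:
        return self.l_ce_cdr + self.l_ce_noncdr

    @property
    def l_total(self) -> float:
        return STRUCTURE_WEIGHT * self.l_structure + self.l_ce_total

    def as_dict(self) -> dict:
        return {
            "l_rmsd": self.l_rmsd, "l_repulsion": self.l_repulsion,
            "l_neighbor": self.l_neighbor, "l_structure": self.l_structure,
            "l_ce_cdr": self.l_ce_cdr, "l_ce_noncdr": self.l_ce_noncdr,
            "l_ce_total": self.l_ce_total, "l_total": self.l_total,
        }


def _rows(mask: np.ndarray, value: int) -> np.ndarray:
    return np.flatnonzero(np.asarray(mask) == value)


def rmsd_loss(trace: ForwardTrace, truth_coords, mask) -> Tensor:
    """Mean over all layers of CDR-restricted RMSD against the truth."""
    cdr = _rows(mask, 1)
    if cdr.size == 0:
        raise UndefinedLossError("no CDR residues to compute RMSD over")
    truth = tensor(np.asarray(truth_coords, dtype=float))[cdr]
    per_layer = []
    for coords in trace.per_layer_coords:
        diff = tensor(coords)[cdr] - truth
        per_layer.append(((diff * diff).sum(axis=1).mean()).sqrt())
    return sum(per_layer[1:], per_layer[0]) / len(per_layer)


def repulsion_loss(trace: ForwardTrace, mask, tau: float = TAU_REPULSION) -> Tensor:
    """Hinge penalty max(τ − d, 0) between CDR and non-CDR atoms.

    Averaged over all CDR×non-CDR pairs, then over layers 5..N.
    """
    cdr, non = _rows(mask, 1), _rows(mask, 0)
    if non.size == 0:
        raise UndefinedLossError("no non-CDR residues for the repulsion loss")
    layers = trace.per_layer_coords[VIOLATION_SKIP_LAYERS:]
    if not layers:
        raise UndefinedLossError("repulsion loss needs more than 4 layers")
    per_layer = []
    for coords in layers:
        x = tensor(coords)
        diff = x[cdr].reshape(cdr.size, 1, 3) - x[non].reshape(1, non.size, 3)
        d = (diff * diff).sum(axis=2).sqrt()
        per_layer.append((tau - d).relu().mean(axis=0).mean())
    return sum(per_layer[1:], per_layer[0]) / len(per_layer)


def neighbor_loss(trace: ForwardTrace, truth_coords, mask) -> Tensor:
    """Consecutive Cα distance deviation along anchor→CDR→anchor.

    For a contiguous CDR of n residues there are n+1 consecutive edges
    including the two anchor-adjacent ones; the loss is the mean absolute
    deviation of the predicted edge lengths from the true ones, averaged
    over layers 5..N.
    """
    cdr = _rows(mask, 1)
    if cdr.size == 0:
        raise UndefinedLossError("no CDR residues for the neighbor loss")
    if not np.array_equal(cdr, np.arange(cdr[0], cdr[-1] + 1)):
        raise ValueError("CDR rows must be contiguous")
    L = np.asarray(truth_coords).shape[0]
    if cdr[0] - 1 < 0 or cdr[-1] + 1 >= L:
        raise ValueError("CDR anchors missing")
    path = np.arange(cdr[0] - 1, cdr[-1] + 2)  # anchor, CDR…, anchor
    truth = np.asarray(truth_coords, dtype=float)[path]
    d_true = np.linalg.norm(truth[1:] - truth[:-1], axis=1)

    layers = trace.per_layer_coords[VIOLATION_SKIP_LAYERS:]
    if not layers:
        raise UndefinedLossError("neighbor loss needs more than 4 layers")
    per_layer = []
    for coords in layers:
        x = tensor(coords)[path]
        seg = x[1:] - x[:-1]
        d_pred = (seg * seg).sum(axis=1).sqrt()
        per_layer.append((d_pred - d_true).abs().mean())
    return sum(per_layer[1:], per_layer[0]) / len(per_layer)


def _smoothed_ce(logits: Tensor, targets: np.ndarray, smoothing: float) -> Tensor:
    """Mean label-smoothed cross-entropy over rows."""
    n_classes = logits.shape[1]
    logp = logits.log_softmax(axis=1)
    onehot = np.eye(n_classes)[targets]
    q = (1.0 - smoothing) * onehot + smoothing / n_classes
    return -(logp * q).sum(axis=1).mean()


def ce_noncdr_loss(
    trace: ForwardTrace, truth_tokens, mask, model: Model,
    smoothing: float = LABEL_SMOOTHING,
) -> Tensor:
    """Label-smoothed CE of the head on non-CDR rows, averaged over all layers."""
    non = _rows(mask, 0)
    targets = np.asarray(truth_tokens)[non]
    per_layer = [
        _smoothed_ce(model.head(tensor(f)[non]), targets, smoothing)
        for f in trace.per_layer_feats
    ]
    return sum(per_layer[1:], per_layer[0]) / len(per_layer)


def ce_cdr_loss(
    trace: ForwardTrace, truth_tokens, mask, model: Model,
    smoothing: float = LABEL_SMOOTHING,
) -> Tensor:
    """Label-smoothed CE of the head on CDR rows, over the last four layers."""
    cdr = _rows(mask, 1)
    targets = np.asarray(truth_tokens)[cdr]
    feats = trace.per_layer_feats[-CE_CDR_LAYERS:]
    per_layer = [
        _smoothed_ce(model.head(tensor(f)[cdr]), targets, smoothing) for f in feats
    ]
    return sum(per_layer[1:], per_layer[0]) / len(per_layer)


def compute_losses(
    trace: ForwardTrace, sample, model: Model,
    tau: float = TAU_REPULSION, smoothing: float = LABEL_SMOOTHING,
) -> tuple[Tensor, LossBreakdown]:
    """All loss terms for one sample; returns (differentiable total, breakdown)."""
    truth, mask, tokens = sample.truth_coords, sample.mask, sample.truth_tokens
    l_rmsd = rmsd_loss(trace, truth, mask)
    l_rep = repulsion_loss(trace, mask, tau=tau)
    l_nei = neighbor_loss(trace, truth, mask)
    l_cdr = ce_cdr_loss(trace, tokens, mask, model, smoothing=smoothing)
    l_non = ce_noncdr_loss(trace, tokens, mask, model, smoothing=smoothing)
    total = STRUCTURE_WEIGHT * (l_rmsd + l_rep + l_nei) + (l_cdr + l_non)
    breakdown = LossBreakdown(
        l_rmsd=float(l_rmsd.data), l_repulsion=float(l_rep.data),
        l_neighbor=float(l_nei.data), l_ce_cdr=float(l_cdr.data),
        l_ce_noncdr=float(l_non.data),
    )
    return total, breakdown


def total_loss(parts: LossBreakdown) -> float:
    """10·(RMSD + repulsion + neighbour) + (CE_cdr + CE_noncdr)."""
    return parts.l_total
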