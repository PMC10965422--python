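"""Convert a (complex, CDR) pair into a masked, model-ready graph sample.

The sample is a residue graph over the design chain, its antibody
partner (if paired), and the antigen residues within a Cα cutoff of the
design chain. CDR residue coordinates are replaced by evenly spaced
points on the line between the two anchor residues and their sequence
tokens by a MASK symbol; the ground truth is kept alongside for the
losses. Edges connect each node to its k nearest neighbours in the
masked coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure_io import (
    AA_TO_INDEX,
    ChainNotFoundError,
    ComplexRecord,
    ChainRecord,
)
from .cdr_schemes import CdrSpec

__all__ = [
    "MASK_TOKEN",
    "GraphSample",
    "select_context",
    "mask_cdr_coords",
    "build_knn_edges",
    "encode_sample",
    "save_sample",
    "load_sample",
]

#: token id of the MASK symbol (amino acids occupy 0..19)
MASK_TOKEN = 20

#: default antigen context cutoff, Å
CONTEXT_CUTOFF = 16.0

#: default neighbourhood size for the residue graph
KNN_NEIGHBORS = 64


class RoleError(ValueError):
    pass


class DegenerateGraphError(ValueError):
    pass


@dataclass
class GraphSample:
    """Model input/target arrays for one CDR design task.

    ``coords`` hold the anchor-line-initialised input (x_input);
    ``truth_coords`` the crystal coordinates. ``mask`` is 1 on CDR rows.
    ``chain_type`` is 0 for antibody rows, 1 for antigen rows. Edges are
    directed (source → target) neighbour pairs.
    """

    coords: np.ndarray        # (L, 3)
    seq_tokens: np.ndarray    # (L,) ints in [0, 20]
    chain_type: np.ndarray    # (L,) ints {0, 1}
    mask: np.ndarray          # (L,) ints {0, 1}
    edges: np.ndarray         # (E, 2) ints, [source, target]
    truth_coords: np.ndarray  # (L, 3)
    truth_tokens: np.ndarray  # (L,) ints in [0, 19]
    index_map: list           # row -> (chain_id, sequential index)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def validate(self) -> None:
        L = self.n_nodes
        assert self.seq_tokens.shape == (L,) and self.mask.shape == (L,)
        assert np.all((self.seq_tokens >= 0) & (self.seq_tokens <= MASK_TOKEN))
        assert np.all(self.seq_tokens[self.mask == 1] == MASK_TOKEN)
        assert np.array_equal(
            self.coords[self.mask == 0], self.truth_coords[self.mask == 0]
        )
        assert not np.any(self.edges[:, 0] == self.edges[:, 1])


def select_context(
    complex_record: ComplexRecord,
    design_chain: str,
    cutoff: float = CONTEXT_CUTOFF,
) -> ComplexRecord:
    """Restrict a complex to the design chain, its partner, and nearby antigen.

    Antigen residues are kept iff their minimum Cα distance to any
    design-chain Cα is ≤ ``cutoff`` (boundary inclusive).
    """
    chain = complex_record.chain(design_chain)
    if not chain.is_antibody:
        raise RoleError(f"design chain {design_chain!r} has role {chain.role!r}")
    partner_id = complex_record.partner_of(design_chain)
    design_xyz = chain.coords()

    kept: list[ChainRecord] = [chain]
    if partner_id is not None:
        kept.append(complex_record.chain(partner_id))
    for other in complex_record.chains:
        if other.role != "antigen":
            continue
        ag_xyz = other.coords()
        dmin = np.linalg.norm(
            ag_xyz[:, None, :] - design_xyz[None, :, :], axis=-1
        ).min(axis=1)
        keep = dmin <= cutoff
        if keep.any():
            kept.append(
                ChainRecord(
                    chain_id=other.chain_id,
                    role="antigen",
                    residues=[r for r, k in zip(other.residues, keep) if k],
                )
            )
    pairing = (
        {design_chain: partner_id}
        if partner_id is not None and chain.role == "heavy"
        else ({partner_id: design_chain} if partner_id is not None else {})
    )
    return ComplexRecord(
        complex_id=complex_record.complex_id, chains=kept, pairing=pairing
    )


def anchor_line_coords(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    """n points evenly spaced strictly between anchors a and b.

    Point i (1-based) sits at a + (b − a)·i/(n+1); the anchors themselves
    are real residues and are excluded.
    """
    fracs = np.arange(1, n + 1, dtype=float) / (n + 1)
    return a[None, :] + (b - a)[None, :] * fracs[:, None]


def mask_cdr_coords(sample: GraphSample, cdr_rows: np.ndarray) -> GraphSample:
    """Apply anchor-line initialisation and MASK tokens to the CDR rows.

    ``cdr_rows`` must be a contiguous run of row indices with both
    flanking rows (anchors) present in the sample.
    """
    rows = np.sort(np.asarray(cdr_rows))
    lo, hi = int(rows[0]), int(rows[-1])
    if lo - 1 < 0 or hi + 1 >= sample.n_nodes:
        raise ValueError("CDR anchors missing from sample")
    a = sample.truth_coords[lo - 1]
    b = sample.truth_coords[hi + 1]
    sample.coords[rows] = anchor_line_coords(a, b, len(rows))
    sample.seq_tokens[rows] = MASK_TOKEN
    sample.mask[:] = 0
    sample.mask[rows] = 1
    return sample


def build_knn_edges(coords: np.ndarray, k_neighbors: int = KNN_NEIGHBORS) -> np.ndarray:
    """Directed edges (neighbor → node) to each node's k nearest others.

    Distances are Euclidean; ties break towards the lower source index.
    Deterministic. Each node receives min(k, L−1) in-edges.
    """
    L = coords.shape[0]
    if L < 2:
        raise DegenerateGraphError("need at least 2 nodes to build edges")
    k = min(k_neighbors, L - 1)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # stable argsort on distance gives lower-index tie-breaking
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    targets = np.repeat(np.arange(L), k)
    sources = order.reshape(-1)
    return np.stack([sources, targets], axis=1)


def encode_sample(
    context: ComplexRecord,
    spec: CdrSpec,
    k_neighbors: int = KNN_NEIGHBORS,
) -> GraphSample:
    """Build the full masked GraphSample for a CDR in a context complex.

    Rows are concatenated design-chain first, then the partner antibody
    chain, then antigen chains, mirroring the chain-length-axis
    concatenation of the input encoding.
    """
    design = context.chain(spec.chain_id)
    partner_id = context.partner_of(spec.chain_id)
    ordered = [design]
    if partner_id is not None:
        ordered.append(context.chain(partner_id))
    ordered.extend(c for c in context.chains if c.role == "antigen")

    truth_coords, tokens, ctype, index_map = [], [], [], []
    for chain in ordered:
        for i, res in enumerate(chain.residues):
            truth_coords.append(res.ca_coord)
            tokens.append(AA_TO_INDEX.get(res.amino_acid, 0))
            ctype.append(0 if chain.is_antibody else 1)
            index_map.append((chain.chain_id, i))
    truth_coords = np.array(truth_coords, dtype=float)
    sample = GraphSample(
        coords=truth_coords.copy(),
        seq_tokens=np.array(tokens, dtype=int),
        chain_type=np.array(ctype, dtype=int),
        mask=np.zeros(len(tokens), dtype=int),
        edges=np.empty((0, 2), dtype=int),
        truth_coords=truth_coords,
        truth_tokens=np.array(tokens, dtype=int),
        index_map=index_map,
    )
    cdr_rows = np.arange(spec.start_idx, spec.end_idx + 1)  # design chain is first
    mask_cdr_coords(sample, cdr_rows)
    sample.edges = build_knn_edges(sample.coords, k_neighbors)
    sample.validate()
    return sample


def save_sample(sample: GraphSample, path) -> Path:
    """Serialize a sample to an .npz container with a JSON index map."""
    path = Path(path)
    np.savez(
        path,
        coords=sample.coords,
        seq_tokens=sample.seq_tokens,
        chain_type=sample.chain_type,
        mask=sample.mask,
        edges=sample.edges,
        truth_coords=sample.truth_coords,
        truth_tokens=sample.truth_tokens,
        index_map=np.frombuffer(
            json.dumps([list(t) for t in sample.index_map]).encode(), dtype=np.uint8
        ),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_sample(path) -> GraphSample:
    with np.load(path) as z:
        index_map = [
            (c, int(i))
            for c, i in json.loads(bytes(z["index_map"].tobytes()).decode())
        ]
        return GraphSample(
            coords=z["coords"], seq_tokens=z["seq_tokens"], chain_type=z["chain_type"],
            mask=z["mask"], edges=z["edges"], truth_coords=z["truth_coords"],
            truth_tokens=z["truth_tokens"], index_map=index_map,
        )
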