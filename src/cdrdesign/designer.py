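"""Inference-time CDR design: coordinate prediction, sequence sampling,
and assembly of the designed chain back into a Cα-level complex.

A single forward pass yields final-layer coordinates for the masked loop
and a 20-way amino-acid distribution per position. Candidate sequences
are drawn independently per position (optionally temperature-scaled);
``temperature=0`` gives the maximum-likelihood sequence. The designed
chain can be merged with the binding context and written as a PDB for
external full-atom reconstruction and relaxation tools.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure_io import (
    AA_ALPHABET,
    ChainRecord,
    ComplexRecord,
    ResidueRecord,
    write_complex_pdb,
)
from .cdr_schemes import CdrSpec
from .graph_prep import CONTEXT_CUTOFF, encode_sample, select_context
from .egnn import Model

__all__ = ["DesignResult", "design_cdr", "assemble_design_chain",
           "full_atom_adapter", "BackendUnavailableError"]


class BackendUnavailableError(RuntimeError):
    """An optional external refinement backend is not installed."""


@dataclass
class DesignResult:
    cdr_coords: np.ndarray          # (n, 3) final-layer masked-row coordinates
    aa_probs: np.ndarray            # (n, 20) rowwise distributions
    sampled_sequences: list[str]
    seed: int
    spec: CdrSpec

    def __post_init__(self):
        if not np.allclose(self.aa_probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("aa_probs rows must sum to 1")
        n = self.cdr_coords.shape[0]
        if any(len(s) != n for s in self.sampled_sequences):
            raise ValueError("sampled sequence length mismatch")


def design_cdr(
    model: Model,
    complex_record: ComplexRecord,
    spec: CdrSpec,
    n_samples: int = 10,
    seed: int = 0,
    temperature: float = 1.0,
    cutoff: float = CONTEXT_CUTOFF,
) -> DesignResult:
    """Design one CDR: one forward pass, then per-position sequence sampling."""
    context = select_context(complex_record, spec.chain_id, cutoff=cutoff)
    sample = encode_sample(context, spec, k_neighbors=model.config.k_neighbors)
    trace = model.forward(sample).numpy()
    rows = np.flatnonzero(sample.mask == 1)
    logits = trace.final_logits[rows]
    if temperature > 0:
        z = logits / temperature
        z = z - z.max(axis=1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    else:  # argmax limit: all mass on the most likely type
        probs = np.zeros_like(logits)
        probs[np.arange(len(rows)), logits.argmax(axis=1)] = 1.0

    rng = np.random.default_rng(seed)
    sequences = []
    for _ in range(n_samples):
        idx = [rng.choice(20, p=p) for p in probs]
        sequences.append("".join(AA_ALPHABET[i] for i in idx))
    return DesignResult(
        cdr_coords=trace.per_layer_coords[-1][rows],
        aa_probs=probs,
        sampled_sequences=sequences,
        seed=seed,
        spec=spec,
    )


def assemble_design_chain(
    complex_record: ComplexRecord,
    result: DesignResult,
    sample_index: int = 0,
    cutoff: float = CONTEXT_CUTOFF,
) -> ComplexRecord:
    """Replace the CDR of the design chain with predicted coords + sequence.

    All non-CDR residues keep their wild-type coordinates and types; the
    returned complex contains the designed chain plus the binding
    context within the cutoff (partner chain and nearby antigen).
    """
    spec = result.spec
    chain = complex_record.chain(spec.chain_id)
    n = spec.end_idx - spec.start_idx + 1
    if result.cdr_coords.shape[0] != n:
        raise ValueError("design length does not match the CDR window")
    sequence = result.sampled_sequences[sample_index]

    new_residues = list(chain.residues)
    for j in range(n):
        old = new_residues[spec.start_idx + j]
        new_residues[spec.start_idx + j] = ResidueRecord(
            chain_id=old.chain_id,
            res_number=old.res_number,
            insertion_code=old.insertion_code,
            amino_acid=sequence[j],
            ca_coord=result.cdr_coords[j],
        )
    designed = ChainRecord(chain.chain_id, chain.role, new_residues)
    merged = ComplexRecord(
        complex_id=f"{complex_record.complex_id}_design",
        chains=[designed if c.chain_id == chain.chain_id else c
                for c in complex_record.chains],
        pairing=complex_record.pairing,
    )
    return select_context(merged, spec.chain_id, cutoff=cutoff)


def full_atom_adapter(assembled: ComplexRecord, backend: str, out_dir) -> Path:
    """Contract point for external full-atom reconstruction/relaxation.

    The core package operates at Cα level only. ``backend="none"``
    writes and returns the Cα-level PDB unchanged. Named backends
    (``pdbfixer``, ``openmm``) are invoked only if importable; a missing
    backend raises :class:`BackendUnavailableError` rather than crashing.

    Users wiring an energy pipeline typically relax the complex several
    times and keep the structure with the minimum estimated binding
    energy; that policy lives entirely on the backend side of this
    contract.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ca_path = write_complex_pdb(assembled, out_dir / f"{assembled.complex_id}_ca.pdb")
    if backend == "none":
        return ca_path
    if backend in ("pdbfixer", "openmm"):
        try:
            __import__(backend)
        except ImportError as exc:
            raise BackendUnavailableError(
                f"backend {backend!r} is not installed; install it or use "
                f"backend='none' for the Cα-level output") from exc
        raise BackendUnavailableError(
            f"backend {backend!r} wiring is not bundled with the core package")
    raise BackendUnavailableError(f"unknown backend {backend!r}")
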