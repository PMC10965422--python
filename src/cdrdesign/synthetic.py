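"""Synthetic antibody-like complexes with learnable loop structure.

The generator emulates, at desk scale, the one statistical regularity
the design model is meant to exploit: hypervariable loops fall into a
small number of canonical conformations, and which conformation (and
sequence) a loop adopts is predictable from its framework context. Each
toy complex has

* a design chain: an idealised Cα trace with exact 3.8 Å virtual bonds,
  whose loop window geometry and sequence are drawn from one of
  ``n_loop_classes`` fixed classes;
* flanking "code" residues on both sides of the loop whose amino-acid
  types deterministically select the class — the learnable signal;
* an antigen chain placed within interaction distance of the loop
  (inside the 16 Å context cutoff, never closer than 3 Å);
* an optional partner antibody chain;
* a random rigid motion of the whole complex and Gaussian coordinate
  noise (σ default 0.1 Å).

Author numbering restarts at 100 after the loop so a fixed numbering
range selects the loop for every class length, the way CDR numbering
schemes absorb loop-length variation with insertion codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import (
    AA_ALPHABET,
    ChainRecord,
    ComplexRecord,
    ResidueRecord,
)
from .cdr_schemes import CdrDefinitionTable, CdrSpec

__all__ = ["ToySpec", "LoopClass", "make_toy_complex", "make_toy_dataset"]

BOND = 3.8  # Cα virtual bond length, Å


@dataclass(frozen=True)
class LoopClass:
    class_id: int
    length: int
    amplitude: float   # max turn angle, rad — controls loop curvature
    plane: float       # orientation of the bulge plane, rad
    sequence: str


@dataclass
class ToySpec:
    n_complexes: int = 200
    design_len_before: int = 14   # framework residues before the loop
    design_len_after: int = 14
    partner_len: int = 8
    antigen_len: int = 10
    cdr_start_number: int = 15    # author number of the first loop residue
    loop_len_range: tuple[int, int] = (6, 9)
    n_loop_classes: int = 6
    flank_code_len: int = 1
    coord_noise_sigma: float = 0.1
    antigen_offset: float = 6.0   # Å from the loop tip
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.n_loop_classes <= 20):
            raise ValueError("n_loop_classes must be in 1..20")
        if self.loop_len_range[0] < 1 or self.loop_len_range[0] > self.loop_len_range[1]:
            raise ValueError("invalid loop_len_range")
        if self.design_len_before < self.flank_code_len + 2:
            raise ValueError("framework too short for flank code + anchor")

    def loop_classes(self) -> list[LoopClass]:
        """The fixed class table; a pure function of the spec seed."""
        rng = np.random.default_rng([self.seed, 0xC1A55])
        lo, hi = self.loop_len_range
        classes = []
        seqs: set[str] = set()
        for c in range(self.n_loop_classes):
            length = lo + c % (hi - lo + 1)
            while True:
                seq = "".join(
                    AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))
                if seq not in seqs:
                    seqs.add(seq)
                    break
            classes.append(LoopClass(
                class_id=c,
                length=length,
                amplitude=0.6 + 1.0 * c / max(self.n_loop_classes - 1, 1),
                plane=2.0 * np.pi * c / self.n_loop_classes,
                sequence=seq,
            ))
        return classes

    def cdr_table(self) -> CdrDefinitionTable:
        """Numbering table selecting the loop window for any class length."""
        return CdrDefinitionTable("toy", {"HCDR3": (self.cdr_start_number, 99)})


def _loop_trace(start: np.ndarray, n: int, amplitude: float, plane: float) -> np.ndarray:
    """Planar arc of n+1 exact-3.8 Å steps starting at ``start`` heading +x.

    Step j turns by a smooth bump of total amplitude ``amplitude``; the
    turning plane is spanned by x̂ and (cos ψ·ŷ + sin ψ·ẑ).
    """
    v = np.array([np.cos(plane), np.sin(plane)])
    pts = [start]
    pos = start.astype(float).copy()
    for j in range(n + 1):
        theta = amplitude * np.sin(np.pi * (j + 0.5) / (n + 1))
        step = BOND * (np.cos(theta) * np.array([1.0, 0.0, 0.0])
                       + np.sin(theta) * np.array([0.0, v[0], v[1]]))
        pos = pos + step
        pts.append(pos.copy())
    return np.array(pts)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _make_chain(chain_id, role, coords, seq, numbers) -> ChainRecord:
    return ChainRecord(chain_id, role, [
        ResidueRecord(chain_id, int(n), "", aa, xyz)
        for n, aa, xyz in zip(numbers, seq, coords)
    ])


def make_toy_complex(
    spec: ToySpec, index: int, rng: np.random.Generator | None = None
) -> tuple[ComplexRecord, CdrSpec, int]:
    """Build toy complex ``index``; reproducible from (spec.seed, index).

    Returns the complex, the loop's CdrSpec on the design chain, and the
    loop class id.
    """
    rng = rng or np.random.default_rng([spec.seed, index])
    classes = spec.loop_classes()
    cls = classes[int(rng.integers(len(classes)))]
    n = cls.length

    # --- design chain: straight framework, class arc, straight framework
    before = np.stack([
        np.array([BOND * i, 0.0, 0.0]) for i in range(spec.design_len_before)])
    loop_and_anchor = _loop_trace(before[-1], n, cls.amplitude, cls.plane)
    loop = loop_and_anchor[1:-1]
    after_start = loop_and_anchor[-1]
    after = np.stack([
        after_start + np.array([BOND * i, 0.0, 0.0])
        for i in range(spec.design_len_after)])
    design_xyz = np.concatenate([before, loop, after])

    code = AA_ALPHABET[cls.class_id]
    seq_before = [
        AA_ALPHABET[i] for i in rng.integers(0, 20, size=spec.design_len_before)]
    seq_before[-spec.flank_code_len:] = [code] * spec.flank_code_len
    seq_after = [
        AA_ALPHABET[i] for i in rng.integers(0, 20, size=spec.design_len_after)]
    seq_after[: spec.flank_code_len] = [code] * spec.flank_code_len
    design_seq = seq_before + list(cls.sequence) + seq_after

    numbers = (
        list(range(1, spec.design_len_before + 1))
        + list(range(spec.cdr_start_number, spec.cdr_start_number + n))
        + list(range(100, 100 + spec.design_len_after))
    )
    assert spec.cdr_start_number > spec.design_len_before
    assert spec.cdr_start_number + n <= 100

    # --- antigen: straight segment beyond the loop tip, pushed out to clearance
    tip = loop[np.argmax(np.linalg.norm(loop - before[-1], axis=1))]
    centroid = design_xyz.mean(axis=0)
    out_dir = tip - centroid
    out_dir = out_dir / np.linalg.norm(out_dir)
    offset = spec.antigen_offset
    while True:
        ag_center = tip + out_dir * offset
        ag = np.stack([
            ag_center + (j - (spec.antigen_len - 1) / 2) * BOND
            * np.array([1.0, 0.0, 0.0]) for j in range(spec.antigen_len)])
        dmin = np.linalg.norm(
            ag[:, None, :] - design_xyz[None, :, :], axis=-1).min()
        if dmin >= 3.0 + 5 * spec.coord_noise_sigma:
            break
        offset += 1.0
    ag_seq = [AA_ALPHABET[i] for i in rng.integers(0, 20, size=spec.antigen_len)]

    chains_xyz = {"H": design_xyz, "A": ag}
    seqs = {"H": design_seq, "A": ag_seq}
    nums = {"H": numbers, "A": list(range(1, spec.antigen_len + 1))}
    if spec.partner_len > 0:
        partner = np.stack([
            np.array([BOND * i, -10.0, 0.0]) for i in range(spec.partner_len)])
        chains_xyz["L"] = partner
        seqs["L"] = [AA_ALPHABET[i] for i in rng.integers(0, 20, size=spec.partner_len)]
        nums["L"] = list(range(1, spec.partner_len + 1))

    # --- random rigid motion + coordinate noise
    R = _random_rotation(rng)
    t = rng.uniform(-10.0, 10.0, size=3)
    for cid in chains_xyz:
        xyz = chains_xyz[cid] @ R.T + t
        xyz = xyz + rng.normal(0.0, spec.coord_noise_sigma, size=xyz.shape)
        chains_xyz[cid] = xyz

    roles = {"H": "heavy", "L": "light", "A": "antigen"}
    record = ComplexRecord(
        complex_id=f"toy{index:05d}",
        chains=[
            _make_chain(cid, roles[cid], chains_xyz[cid], seqs[cid], nums[cid])
            for cid in chains_xyz
        ],
        pairing={"H": "L"} if spec.partner_len > 0 else {},
    )
    cdr = CdrSpec(
        chain_id="H", cdr_name="HCDR3",
        start_idx=spec.design_len_before,
        end_idx=spec.design_len_before + n - 1,
        scheme="toy",
    )
    return record, cdr, cls.class_id


def make_toy_dataset(
    spec: ToySpec,
) -> tuple[list[ComplexRecord], list[CdrSpec], list[int], dict]:
    """Generate n_complexes toy complexes plus a chain-role manifest."""
    records, cdrs, class_ids = [], [], []
    for i in range(spec.n_complexes):
        rec, cdr, cid = make_toy_complex(spec, i)
        records.append(rec)
        cdrs.append(cdr)
        class_ids.append(cid)
    manifest = {
        rec.complex_id: {c.chain_id: c.role for c in rec.chains} for rec in records
    }
    return records, cdrs, class_ids, manifest
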