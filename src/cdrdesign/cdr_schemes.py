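"""CDR location under standard numbering schemes and flexible-anchor augmentation.

A CDR is located by its author-numbering range under a numbering scheme
(Chothia or IMGT by default; the table is overridable). Augmentation
produces every variant obtained by shifting the two anchor residues
independently within ±k sequential positions — up to (2k+1)² variants
per CDR — which exposes the model to many boundary definitions of the
same loop instead of a single scheme's convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio import Align

from .structure_io import (
    ChainRecord,
    ComplexRecord,
    ChainNotFoundError,
    check_cdr_completeness,
)

__all__ = [
    "CDR_NAMES",
    "CdrSpec",
    "CdrDefinitionTable",
    "DEFAULT_TABLES",
    "default_table",
    "locate_cdr",
    "augment_anchors",
    "cdr_sequence",
    "build_pair_dataset",
    "sequence_identity",
]

CDR_NAMES = ("HCDR1", "HCDR2", "HCDR3", "LCDR1", "LCDR2", "LCDR3")

#: default anchor-shift threshold k for augmentation
DEFAULT_K = 5


class CdrNotFoundError(ValueError):
    """No residues fall in the scheme's numbering range, or role mismatch."""


class AnchorError(ValueError):
    """A CDR lies at a chain terminus and lacks a flanking anchor residue."""


@dataclass(frozen=True)
class CdrSpec:
    """One CDR instance on a chain, in sequential (0-based) coordinates.

    ``start_idx``/``end_idx`` are inclusive positions in the chain's
    residue list; ``shift`` records the (δ_start, δ_end) anchor offsets
    relative to the unaugmented scheme definition.
    """

    chain_id: str
    cdr_name: str
    start_idx: int
    end_idx: int
    scheme: str = "chothia"
    shift: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.cdr_name not in CDR_NAMES:
            raise ValueError(f"cdr_name must be one of {CDR_NAMES}")
        if self.start_idx > self.end_idx:
            raise ValueError("start_idx must be ≤ end_idx")
        if self.start_idx < 1:
            raise AnchorError("start anchor (start_idx-1) would fall off the chain")

    @property
    def length(self) -> int:
        return self.end_idx - self.start_idx + 1


# (scheme, cdr_name) -> (start res_number, end res_number), author numbering,
# insertion codes inside the range included. Community-standard loop ranges.
_CHOTHIA = {
    "HCDR1": (26, 32), "HCDR2": (52, 56), "HCDR3": (95, 102),
    "LCDR1": (24, 34), "LCDR2": (50, 56), "LCDR3": (89, 97),
}
_IMGT = {
    "HCDR1": (27, 38), "HCDR2": (56, 65), "HCDR3": (105, 117),
    "LCDR1": (27, 38), "LCDR2": (56, 65), "LCDR3": (105, 117),
}


@dataclass(frozen=True)
class CdrDefinitionTable:
    scheme: str
    ranges: dict  # cdr_name -> (start_num, end_num)

    def range_for(self, cdr_name: str) -> tuple[int, int]:
        if cdr_name not in self.ranges:
            raise CdrNotFoundError(f"{self.scheme} table has no range for {cdr_name}")
        return self.ranges[cdr_name]


DEFAULT_TABLES = {
    "chothia": CdrDefinitionTable("chothia", _CHOTHIA),
    "imgt": CdrDefinitionTable("imgt", _IMGT),
}


def default_table(scheme: str = "chothia") -> CdrDefinitionTable:
    try:
        return DEFAULT_TABLES[scheme]
    except KeyError:
        raise CdrNotFoundError(f"no default table for scheme {scheme!r}") from None


def load_table_file(path, scheme: str) -> CdrDefinitionTable:
    """Load a numbering table from YAML: {scheme: {cdr_name: [start, end]}}."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if scheme not in data:
        raise CdrNotFoundError(f"table file has no scheme {scheme!r}")
    ranges = {name: tuple(rng) for name, rng in data[scheme].items()}
    return CdrDefinitionTable(scheme, ranges)


def write_table_file(table: CdrDefinitionTable, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({table.scheme: {k: list(v) for k, v in table.ranges.items()}}, fh)


def locate_cdr(
    chain: ChainRecord,
    cdr_name: str,
    scheme: str = "chothia",
    table: CdrDefinitionTable | None = None,
) -> CdrSpec:
    """Locate a CDR on a chain by author numbering under a scheme table."""
    expected_role = "heavy" if cdr_name.startswith("H") else "light"
    if chain.role != expected_role:
        raise CdrNotFoundError(
            f"{cdr_name} requested on a {chain.role} chain ({chain.chain_id})"
        )
    table = table or default_table(scheme)
    lo, hi = table.range_for(cdr_name)
    idxs = [i for i, r in enumerate(chain.residues) if lo <= r.res_number <= hi]
    if not idxs:
        raise CdrNotFoundError(
            f"no residues numbered {lo}..{hi} on chain {chain.chain_id}"
        )
    start_idx, end_idx = min(idxs), max(idxs)
    if start_idx - 1 < 0 or end_idx + 1 > len(chain) - 1:
        raise AnchorError(f"{cdr_name} on chain {chain.chain_id} lacks an anchor")
    return CdrSpec(chain.chain_id, cdr_name, start_idx, end_idx, scheme=scheme)


def augment_anchors(base: CdrSpec, k: int, chain_len: int) -> list[CdrSpec]:
    """All anchor-shifted variants of ``base`` with shifts in [−k, k]².

    A variant is retained iff its window is non-empty and both shifted
    anchors still exist on the chain. At most (2k+1)² variants; the
    unshifted base is always present when it is itself valid.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if base.shift != (0, 0):
        raise ValueError("augment_anchors expects an unaugmented base spec")
    variants = []
    for d_start in range(-k, k + 1):
        for d_end in range(-k, k + 1):
            s = base.start_idx + d_start
            e = base.end_idx + d_end
            if s > e or s - 1 < 0 or e + 1 > chain_len - 1:
                continue
            variants.append(
                replace(base, start_idx=s, end_idx=e,
                        scheme="augmented" if (d_start, d_end) != (0, 0) else base.scheme,
                        shift=(d_start, d_end))
            )
    return variants


def cdr_sequence(chain: ChainRecord, spec: CdrSpec) -> str:
    """Amino-acid string of the CDR window (inclusive of both ends)."""
    if spec.start_idx < 0 or spec.end_idx >= len(chain):
        raise IndexError(f"spec {spec} out of bounds for chain of length {len(chain)}")
    return "".join(r.amino_acid for r in chain.residues[spec.start_idx:spec.end_idx + 1])


_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=0,
    open_gap_score=0, extend_gap_score=0,
)


def sequence_identity(a: str, b: str) -> float:
    """Global (Needleman–Wunsch) identity: matches / aligned columns."""
    if not a or not b:
        return 0.0
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    aligned_len = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / aligned_len if aligned_len else 0.0


def build_pair_dataset(
    complexes: list[ComplexRecord],
    table: CdrDefinitionTable | None = None,
    k: int = DEFAULT_K,
    test_cdr_sequences: set[str] | frozenset = frozenset(),
    similarity_threshold: float | None = None,
    cdr_names: tuple[str, ...] = CDR_NAMES,
) -> list[tuple[CdrSpec, ComplexRecord]]:
    """Expand complexes into (CdrSpec, ComplexRecord) training pairs.

    Every locatable, complete CDR is augmented with anchor shifts up to
    ±k. Pairs whose CDR sequence is identical to any held-out test
    sequence are removed; if ``similarity_threshold`` is given, pairs
    with global alignment identity ≥ threshold to any test sequence are
    removed as well (the strict-split variant).
    """
    test_cdr_sequences = set(test_cdr_sequences)
    pairs: list[tuple[CdrSpec, ComplexRecord]] = []
    for cx in complexes:
        for chain in cx.chains:
            if not chain.is_antibody:
                continue
            for name in cdr_names:
                if (name.startswith("H")) != (chain.role == "heavy"):
                    continue
                try:
                    base = locate_cdr(chain, name, table=table or default_table())
                except (CdrNotFoundError, AnchorError):
                    continue
                if not check_cdr_completeness(cx, base):
                    continue
                for spec in augment_anchors(base, k, len(chain)):
                    seq = cdr_sequence(chain, spec)
                    if seq in test_cdr_sequences:
                        continue
                    if similarity_threshold is not None and any(
                        sequence_identity(seq, t) >= similarity_threshold
                        for t in test_cdr_sequences
                    ):
                        continue
                    pairs.append((spec, cx))
    if not pairs:
        import warnings

        warnings.warn("build_pair_dataset produced an empty dataset")
    return pairs


def write_pair_manifest(pairs, complexes_by_id, path) -> None:
    """Write a tab-separated manifest: complex_id, chain_id, cdr_name, δs, δe, seq."""
    with open(path, "w") as fh:
        fh.write("complex_id\tchain_id\tcdr_name\tdelta_start\tdelta_end\tsequence\n")
        for spec, cx in pairs:
            seq = cdr_sequence(cx.chain(spec.chain_id), spec)
            fh.write(
                f"{cx.complex_id}\t{spec.chain_id}\t{spec.cdr_name}\t"
                f"{spec.shift[0]}\t{spec.shift[1]}\t{seq}\n"
            )
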