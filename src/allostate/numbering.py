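"""Map LDH/MalDH-family sequences onto the normalized residue numbering.

The family literature compares catalytic positions (68, 102, 199, 246,
250, ...) across proteins using a shared "normalized" numbering defined on
a canonical lactate-dehydrogenase reference. This module builds the
bidirectional correspondence between a query sequence's own 1-based
indices and that normalized numbering via global pairwise alignment
against a packaged reference profile.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError

__all__ = [
    "ReferenceProfile",
    "ResidueMap",
    "AlignParams",
    "load_reference",
    "build_residue_map",
    "residue_at",
]

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYXBZ")


@dataclass(frozen=True)
class ReferenceProfile:
    """A reference sequence annotated with normalized residue numbers."""

    reference_id: str
    sequence: str
    normalized_numbers: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.normalized_numbers):
            raise InputError(
                "reference sequence and normalized_numbers differ in length: "
                f"{len(self.sequence)} vs {len(self.normalized_numbers)}"
            )
        nums = self.normalized_numbers
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise InputError("normalized_numbers must be strictly increasing")

    @property
    def normalized_range(self) -> tuple[int, int]:
        return self.normalized_numbers[0], self.normalized_numbers[-1]

    def residue_at_normalized(self, normalized: int) -> str:
        try:
            i = self.normalized_numbers.index(normalized)
        except ValueError as exc:
            raise InputError(
                f"normalized number {normalized} not present in reference "
                f"{self.reference_id}"
            ) from exc
        return self.sequence[i]


def load_reference(name: str = "builtin:ldh") -> ReferenceProfile:
    """Load a packaged (``builtin:ldh``) or on-disk JSON reference profile."""
    if name == "builtin:ldh":
        text = (
            resources.files("allostate.data")
            .joinpath("reference_ldh.json")
            .read_text()
        )
    else:
        with open(name) as fh:
            text = fh.read()
    raw = json.loads(text)
    return ReferenceProfile(
        reference_id=raw["reference_id"],
        sequence=raw["sequence"],
        normalized_numbers=tuple(raw["normalized_numbers"]),
    )


@dataclass(frozen=True)
class AlignParams:
    """Scoring configuration for the query-to-reference global alignment.

    End gaps are free, which is the standard choice when slotting a
    single-domain query onto a same-superfamily reference.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    identity_floor: float = 0.15


@dataclass(frozen=True)
class ResidueMap:
    """Bidirectional query-index <-> normalized-number correspondence.

    ``pairs`` holds (query_index, normalized_number) for every aligned
    column; both coordinates are strictly increasing (colinearity).
    ``unmapped_query`` lists query residues falling in insertions
    relative to the reference.
    """

    query_id: str
    pairs: tuple[tuple[int, int], ...]
    unmapped_query: tuple[int, ...]
    reference_id: str
    normalized_range: tuple[int, int]
    identity: float
    low_identity: bool = False
    _by_normalized: dict = field(default_factory=dict, repr=False, compare=False)
    _by_query: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        qs = [q for q, _ in self.pairs]
        ns = [n for _, n in self.pairs]
        if any(b <= a for a, b in zip(qs, qs[1:])):
            raise InputError("query indices in pairs must be strictly increasing")
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise InputError("normalized numbers in pairs must be strictly increasing")
        object.__setattr__(self, "_by_normalized", {n: q for q, n in self.pairs})
        object.__setattr__(self, "_by_query", {q: n for q, n in self.pairs})

    def query_index(self, normalized: int) -> int | None:
        """1-based query index at a normalized number, None if deleted."""
        lo, hi = self.normalized_range
        if not lo <= normalized <= hi:
            raise InputError(
                f"normalized number {normalized} outside reference range "
                f"[{lo}, {hi}]"
            )
        return self._by_normalized.get(normalized)

    def normalized_number(self, query_index: int) -> int | None:
        return self._by_query.get(query_index)

    def to_records(self) -> list[dict]:
        return [
            {"query_index": q, "normalized_number": n} for q, n in self.pairs
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "query_id": self.query_id,
                "reference_id": self.reference_id,
                "identity": self.identity,
                "low_identity": self.low_identity,
                "pairs": [list(p) for p in self.pairs],
                "unmapped_query": list(self.unmapped_query),
            },
            indent=1,
        )


def _validate_sequence(seq: str, min_length: int = 30) -> str:
    if not seq:
        raise InputError("empty sequence")
    seq = seq.upper().strip("*")
    bad = set(seq) - _VALID_AA
    if bad:
        raise InputError(f"invalid amino-acid letters in sequence: {sorted(bad)}")
    if len(seq) < min_length:
        raise InputError(
            f"sequence too short for family mapping ({len(seq)} < {min_length})"
        )
    return seq


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.end_gap_score = 0.0  # free end gaps on both sequences
    return aligner


def build_residue_map(
    query: str,
    ref: ReferenceProfile,
    align_params: AlignParams | None = None,
    query_id: str = "query",
) -> ResidueMap:
    """Globally align ``query`` to the reference and return the ResidueMap.

    Every aligned (non-gap/non-gap) column contributes one
    (query_index, normalized_number) pair. Query residues aligned to
    reference gaps (insertions) land in ``unmapped_query``. If alignment
    identity drops below the configured floor the map is flagged
    ``low_identity`` (family membership doubtful) and a warning is issued.
    """
    params = align_params or AlignParams()
    seq = _validate_sequence(query)
    aligner = _make_aligner(params)
    alignment = next(iter(aligner.align(ref.sequence, seq)))

    pairs: list[tuple[int, int]] = []
    mapped_query: set[int] = set()
    n_ident = 0
    for (rs, re_), (qs, qe) in zip(*alignment.aligned):
        for k in range(re_ - rs):
            ri, qi = rs + k, qs + k
            pairs.append((int(qi) + 1, int(ref.normalized_numbers[ri])))
            mapped_query.add(qi + 1)
            if ref.sequence[ri] == seq[qi]:
                n_ident += 1
    unmapped = tuple(i for i in range(1, len(seq) + 1) if i not in mapped_query)
    identity = n_ident / len(pairs) if pairs else 0.0
    low = identity < params.identity_floor
    if low:
        warnings.warn(
            f"{query_id}: alignment identity {identity:.1%} below floor "
            f"{params.identity_floor:.0%}; family membership doubtful",
            stacklevel=2,
        )
    return ResidueMap(
        query_id=query_id,
        pairs=tuple(pairs),
        unmapped_query=unmapped,
        reference_id=ref.reference_id,
        normalized_range=ref.normalized_range,
        identity=identity,
        low_identity=low,
    )


def residue_at(rmap: ResidueMap, seq: str, normalized: int) -> str | None:
    """Amino acid of ``seq`` occupying a normalized position (None if deleted)."""
    qi = rmap.query_index(normalized)
    if qi is None:
        return None
    return seq[qi - 1]


def iter_fasta(path: str) -> Iterable[tuple[str, str]]:
    """Yield (id, sequence) records from a FASTA file."""
    from Bio import SeqIO

    for rec in SeqIO.parse(path, "fasta"):
        yield rec.id, str(rec.seq)
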