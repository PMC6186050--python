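"""Core domain objects shared across the pipeline.

All coordinates are 0-based, half-open. Sequences are uppercase; the
reference alphabet is ACGTN and the ancestral alphabet additionally allows
'-' for unaligned columns ('N' and '-' are both treated as unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNKNOWN_CODE = 4
REF_ALPHABET = frozenset("ACGTN")
ANC_ALPHABET = frozenset("ACGTN-")

DERIVED = "derived"
SIMULATED = "simulated"
EXTERNAL = "external"
LABELS = (DERIVED, SIMULATED, EXTERNAL)


class SpeciesCaddError(Exception):
    """Base class for contract violations raised by this package."""


class ParseError(SpeciesCaddError):
    """A file could not be parsed under the expected dialect."""


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes: A,C,G,T -> 0..3, other -> 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(raw.shape, UNKNOWN_CODE, dtype=np.int8)
    for base, code in BASE_INDEX.items():
        out[raw == ord(base)] = code
    return out


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


@dataclass
class GenomeSequence:
    """A reference genome: ordered mapping of contig name to ACGTN sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise SpeciesCaddError("genome has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise SpeciesCaddError(f"contig {name!r} is empty")
            bad = set(seq) - REF_ALPHABET
            if bad:
                raise SpeciesCaddError(
                    f"contig {name!r} contains invalid characters {sorted(bad)}"
                )
        self._codes: dict[str, np.ndarray] = {}

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def names(self) -> list[str]:
        return list(self.contigs)

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def codes(self, name: str) -> np.ndarray:
        """Integer codes for a contig, cached."""
        if name not in self._codes:
            self._codes[name] = encode(self.contigs[name])
        return self._codes[name]


@dataclass
class AncestorAlignment:
    """Ancestral states projected onto reference coordinates.

    One string per reference contig, same length; '-' marks unaligned
    columns and is equivalent to 'N' (unknown ancestral state).
    """

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise SpeciesCaddError("ancestor alignment has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise SpeciesCaddError(f"ancestor contig {name!r} is empty")
            bad = set(seq) - ANC_ALPHABET
            if bad:
                raise SpeciesCaddError(
                    f"ancestor contig {name!r} contains invalid characters {sorted(bad)}"
                )
        self._codes: dict[str, np.ndarray] = {}

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def names(self) -> list[str]:
        return list(self.contigs)

    def codes(self, name: str) -> np.ndarray:
        if name not in self._codes:
            self._codes[name] = encode(self.contigs[name])
        return self._codes[name]

    def validate_against(self, ref: GenomeSequence) -> None:
        """Check the pairing invariants: same contig set, equal lengths."""
        if set(self.contigs) != set(ref.contigs):
            only_ref = set(ref.contigs) - set(self.contigs)
            only_anc = set(self.contigs) - set(ref.contigs)
            raise SpeciesCaddError(
                f"contig sets differ (reference only: {sorted(only_ref)}, "
                f"ancestor only: {sorted(only_anc)})"
            )
        for name, seq in self.contigs.items():
            if len(seq) != ref.length(name):
                raise SpeciesCaddError(
                    f"length mismatch on {name!r}: reference {ref.length(name)}, "
                    f"ancestor {len(seq)}"
                )


@dataclass
class Variant:
    """A single-nucleotide variant in 0-based reference coordinates.

    ``label`` records its training class: ``derived`` (reference differs
    from the inferred ancestor; proxy-benign), ``simulated`` (drawn from the
    neutral substitution model; proxy-deleterious) or ``external``.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    label: str = EXTERNAL
    consequence: str | None = None
    af: float | None = None
    transcribed: bool = False
    translated: bool = False
    fold: int | None = None

    def __post_init__(self) -> None:
        if self.ref_allele not in BASE_INDEX or self.alt_allele not in BASE_INDEX:
            raise SpeciesCaddError(
                f"alleles must be single ACGT bases, got "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise SpeciesCaddError(f"ref and alt alleles identical at {self.contig}:{self.pos}")
        if self.pos < 0:
            raise SpeciesCaddError(f"negative position {self.pos}")
        if self.label not in LABELS:
            raise SpeciesCaddError(f"unknown label {self.label!r}")
        if self.af is not None and not 0.0 <= self.af <= 1.0:
            raise SpeciesCaddError(f"allele frequency {self.af} outside [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref_allele}:{self.alt_allele}"

    def with_fold(self, fold: int) -> "Variant":
        return replace(self, fold=fold)


PER_BASE_SCORE = "per_base_score"
INTERVAL = "interval"


@dataclass
class Track:
    """A genomic annotation track: per-base scores or presence intervals.

    ``data`` maps contig name to (starts, ends, values) arrays for
    per-base-score tracks and (starts, ends) for interval tracks. Records
    are half-open; per-base records must be sorted and non-overlapping.
    """

    name: str
    kind: str
    data: dict[str, tuple[np.ndarray, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in (PER_BASE_SCORE, INTERVAL):
            raise SpeciesCaddError(f"unknown track kind {self.kind!r}")

    @classmethod
    def per_base(
        cls, name: str, records: list[tuple[str, int, int, float]]
    ) -> "Track":
        by_contig: dict[str, list[tuple[int, int, float]]] = {}
        for contig, start, end, value in records:
            _check_interval(contig, start, end)
            by_contig.setdefault(contig, []).append((start, end, value))
        data = {}
        for contig, recs in by_contig.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            values = np.array([r[2] for r in recs], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                raise SpeciesCaddError(
                    f"track {name!r}: overlapping score records on {contig!r}"
                )
            data[contig] = (starts, ends, values)
        return cls(name=name, kind=PER_BASE_SCORE, data=data)

    @classmethod
    def intervals(cls, name: str, records: list[tuple[str, int, int]]) -> "Track":
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in records:
            _check_interval(contig, start, end)
            by_contig.setdefault(contig, []).append((start, end))
        data = {}
        for contig, recs in by_contig.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            data[contig] = (starts, ends)
        return cls(name=name, kind=INTERVAL, data=data)

    def lookup(self, contig: str, pos: int) -> float | None:
        """Score covering pos (or None) for score tracks; 0/1 coverage for intervals."""
        if self.kind == PER_BASE_SCORE:
            if contig not in self.data:
                return None
            starts, ends, values = self.data[contig]
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos < ends[i]:
                return float(values[i])
            return None
        starts_ends = self.data.get(contig)
        if starts_ends is None:
            return 0.0
        starts, ends = starts_ends
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        # intervals may overlap, so scan left over all candidates with start <= pos
        while i >= 0:
            if pos < ends[i]:
                return 1.0
            i -= 1
        return 0.0

    def iter_records(self) -> Iterator[tuple]:
        for contig in sorted(self.data):
            arrays = self.data[contig]
            for row in zip(*(a.tolist() for a in arrays)):
                yield (contig, *row)


def _check_interval(contig: str, start: int, end: int) -> None:
    if start < 0:
        raise SpeciesCaddError(f"negative interval start {start} on {contig!r}")
    if end <= start:
        raise SpeciesCaddError(
            f"interval end {end} <= start {start} on {contig!r}"
        )
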