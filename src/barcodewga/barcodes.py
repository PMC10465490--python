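"""Design and validation of error-correcting DNA cell barcodes.

Cell barcodes are short fixed-length DNA words prepended to amplification
primers. To survive sequencing errors at the barcode position the set must
keep a minimum pairwise Hamming distance d, which guarantees correction of
up to floor((d-1)/2) substitutions. Words with long homopolymer runs or
extreme GC content synthesize and sequence poorly and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable

ALPHABET = "ACGT"


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def gc_fraction(word: str) -> float:
    return sum(c in "GC" for c in word) / len(word)


def max_homopolymer_run(word: str) -> int:
    best = run = 1
    for prev, cur in zip(word, word[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class BarcodeConstraints:
    """Constraints a barcode set must satisfy.

    Parameters
    ----------
    length : int
        Barcode length in nucleotides.
    min_distance : int
        Minimum pairwise Hamming distance between any two barcodes.
    max_homopolymer : int
        Longest allowed single-base run (runs longer than this are excluded).
    gc_min, gc_max : float
        Inclusive bounds on the allowed GC fraction; words with GC strictly
        below ``gc_min`` or strictly above ``gc_max`` are excluded.
    """

    length: int = 6
    min_distance: int = 3
    max_homopolymer: int = 3
    gc_min: float = 0.10
    gc_max: float = 0.90

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        if not 1 <= self.min_distance <= self.length:
            raise ValueError("min_distance must satisfy 1 <= d <= length")
        if self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be positive")
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min < gc_max <= 1")

    def word_ok(self, word: str) -> bool:
        """Whether a single word passes the composition filters."""
        if max_homopolymer_run(word) > self.max_homopolymer:
            return False
        g = gc_fraction(word)
        return self.gc_min <= g <= self.gc_max


@dataclass
class BarcodeSet:
    """An ordered set of same-length DNA barcodes plus its constraints."""

    barcodes: list[str]
    constraints: BarcodeConstraints = field(default_factory=BarcodeConstraints)

    def __post_init__(self) -> None:
        self.barcodes = [b.upper() for b in self.barcodes]
        for b in self.barcodes:
            if set(b) - set(ALPHABET):
                raise ValueError(f"barcode {b!r} has non-ACGT symbols")

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    @property
    def length(self) -> int:
        return self.constraints.length


@dataclass
class ValidationReport:
    min_pairwise_distance: int
    correctable_errors: int
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def design_barcodes(constraints: BarcodeConstraints) -> BarcodeSet:
    """Greedy lexicographic barcode design.

    Enumerates all ``4**length`` words in lexicographic order (A<C<G<T),
    drops words failing the homopolymer/GC filters, and accepts a word iff
    its Hamming distance to every previously accepted word is at least
    ``min_distance``. Deterministic; returns the maximal greedy set.
    """
    accepted: list[str] = []
    for letters in product(ALPHABET, repeat=constraints.length):
        word = "".join(letters)
        if not constraints.word_ok(word):
            continue
        if all(hamming(word, prev) >= constraints.min_distance for prev in accepted):
            accepted.append(word)
    return BarcodeSet(accepted, constraints)


def validate_barcode_set(bset: BarcodeSet) -> ValidationReport:
    """Check a barcode set against its constraints.

    Reports the exact minimum pairwise Hamming distance, the number of
    substitution errors guaranteed correctable (floor((d-1)/2)), and every
    length / homopolymer / GC / duplicate violation found.
    """
    barcodes = bset.barcodes
    if not barcodes:
        raise ValueError("empty barcode set")
    cons = bset.constraints
    violations: list[str] = []
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise ValueError(f"barcodes of unequal length: {sorted(lengths)}")
    if lengths != {cons.length}:
        violations.append(
            f"barcode length {lengths.pop()} != constraint length {cons.length}"
        )
    seen: set[str] = set()
    for b in barcodes:
        if b in seen:
            violations.append(f"duplicate barcode {b}")
        seen.add(b)
        if max_homopolymer_run(b) > cons.max_homopolymer:
            violations.append(
                f"{b}: homopolymer run {max_homopolymer_run(b)} > {cons.max_homopolymer}"
            )
        g = gc_fraction(b)
        if not cons.gc_min <= g <= cons.gc_max:
            violations.append(f"{b}: GC fraction {g:.3f} outside "
                              f"[{cons.gc_min}, {cons.gc_max}]")

    if len(barcodes) >= 2:
        min_d = min(
            hamming(a, b)
            for i, a in enumerate(barcodes)
            for b in barcodes[i + 1:]
        )
    else:
        min_d = len(barcodes[0])
    if min_d < cons.min_distance:
        violations.append(
            f"min pairwise distance {min_d} < required {cons.min_distance}"
        )
    return ValidationReport(
        min_pairwise_distance=min_d,
        correctable_errors=(min_d - 1) // 2,
        violations=violations,
    )


def write_barcode_tsv(bset: BarcodeSet | Iterable[str], path) -> None:
    """Write barcodes as TSV with columns ``barcode_id, sequence``."""
    with open(path, "w") as fh:
        fh.write("barcode_id\tsequence\n")
        for i, seq in enumerate(bset, start=1):
            fh.write(f"bc{i:03d}\t{seq}\n")


def read_barcode_tsv(path) -> dict[str, str]:
    """Read a barcode TSV back as an ordered ``{barcode_id: sequence}`` map."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["barcode_id", "sequence"]:
            raise ValueError(f"unexpected barcode TSV header: {header}")
        for line in fh:
            if not line.strip():
                continue
            bc_id, seq = line.rstrip("\n").split("\t")[:2]
            out[bc_id] = seq.upper()
    return out
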