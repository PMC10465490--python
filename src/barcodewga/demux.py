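"""Demultiplexing of barcoded read pairs.

The cell barcode occupies the first ``length`` bases of read 2. Reads are
assigned to the unique barcode within a configurable Hamming distance
(default 1 mismatch, safe for a distance-3 design), the barcode is trimmed
from read 2, and per-barcode streams plus a conservation-checked report are
produced. Also includes the barcode-swap assessment for mixed-species
experiments and the multiplexing cost arithmetic.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .barcodes import BarcodeSet, hamming

UNASSIGNED = "UNASSIGNED"
AMBIGUOUS = "AMBIGUOUS"

_VALID_PREFIX = set("ACGTN")


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: seq/qual length mismatch")


@dataclass
class DemuxReport:
    per_barcode_counts: Counter = field(default_factory=Counter)
    n_unassigned: int = 0
    n_ambiguous: int = 0
    status_counts: Counter = field(default_factory=Counter)

    @property
    def n_total(self) -> int:
        return sum(self.per_barcode_counts.values()) + self.n_unassigned + self.n_ambiguous

    def to_dict(self) -> dict:
        return {
            "per_barcode_counts": dict(self.per_barcode_counts),
            "n_unassigned": self.n_unassigned,
            "n_ambiguous": self.n_ambiguous,
            "n_total": self.n_total,
            "status_counts": dict(self.status_counts),
        }


@dataclass
class SwapAssessment:
    rate_truthA_under_B: float
    rate_truthB_under_A: float
    expected_ratio_uniform: float
    n_under_A: int
    n_under_B: int
    flags: list[str] = field(default_factory=list)


def _barcode_map(bset: BarcodeSet | dict[str, str]) -> dict[str, str]:
    if isinstance(bset, BarcodeSet):
        return {f"bc{i:03d}": seq for i, seq in enumerate(bset.barcodes, start=1)}
    return dict(bset)


def assign_barcode(
    prefix: str,
    bset: BarcodeSet | dict[str, str],
    max_mismatch: int = 1,
) -> str:
    """Assign a read-2 prefix to a barcode id.

    Returns the unique barcode id within Hamming distance ``max_mismatch``,
    ``UNASSIGNED`` if there is none, or ``AMBIGUOUS`` if several barcodes tie
    (possible only when ``max_mismatch`` exceeds the safe correction radius
    floor((d-1)/2); ties are never broken silently). 'N' mismatches every base.
    """
    prefix = prefix.upper()
    if set(prefix) - _VALID_PREFIX:
        raise ValueError(f"prefix {prefix!r} contains non-ACGTN symbols")
    codes = _barcode_map(bset)
    hits = []
    for bc_id, seq in codes.items():
        if len(prefix) != len(seq):
            raise ValueError(
                f"prefix length {len(prefix)} != barcode length {len(seq)}"
            )
        # N never matches, so hamming() counts it as a mismatch already
        if hamming(prefix, seq) <= max_mismatch:
            hits.append(bc_id)
    if not hits:
        return UNASSIGNED
    if len(hits) > 1:
        return AMBIGUOUS
    return hits[0]


def demultiplex(
    reads: Iterable[ReadPair],
    bset: BarcodeSet | dict[str, str],
    max_mismatch: int = 1,
) -> tuple[dict[str, list[ReadPair]], DemuxReport]:
    """Split read pairs by barcode, trimming the barcode from read 2.

    Every input read lands in exactly one output class (a barcode id,
    unassigned, or ambiguous); the report conserves totals. Read 2 of
    assigned reads is shortened by the barcode length. Reads whose read 2 is
    shorter than the barcode are counted unassigned.
    """
    codes = _barcode_map(bset)
    blen = len(next(iter(codes.values())))
    out: dict[str, list[ReadPair]] = {bc_id: [] for bc_id in codes}
    report = DemuxReport()
    for rp in reads:
        if len(rp.seq2) < blen:
            report.n_unassigned += 1
            continue
        call = assign_barcode(rp.seq2[:blen], codes, max_mismatch)
        if call == UNASSIGNED:
            report.n_unassigned += 1
        elif call == AMBIGUOUS:
            report.n_ambiguous += 1
        else:
            report.per_barcode_counts[call] += 1
            out[call].append(
                ReadPair(rp.read_id, rp.seq1, rp.qual1,
                         rp.seq2[blen:], rp.qual2[blen:])
            )
    return out, report


def classify_barcoding_status(
    reads: Iterable[ReadPair],
    expected: str,
    bset: BarcodeSet | dict[str, str],
    max_mismatch: int = 1,
) -> Counter:
    """Classify each read as expected / other_known_barcode / unassigned.

    Mirrors the single-plex barcoding-status QC: a library amplified under
    one barcode is sequenced and each read's prefix is checked against the
    whole design.
    """
    codes = _barcode_map(bset)
    if expected not in codes:
        raise ValueError(f"expected barcode {expected!r} not in set")
    blen = len(codes[expected])
    status: Counter = Counter({"expected": 0, "other_known_barcode": 0, "unassigned": 0})
    for rp in reads:
        if len(rp.seq2) < blen:
            status["unassigned"] += 1
            continue
        call = assign_barcode(rp.seq2[:blen], codes, max_mismatch)
        if call == expected:
            status["expected"] += 1
        elif call in (UNASSIGNED, AMBIGUOUS):
            status["unassigned"] += 1
        else:
            status["other_known_barcode"] += 1
    return status


def estimate_swap_ratio(
    assignments: Iterable[tuple[str, str]],
    groupA_barcodes: set[str],
    groupB_barcodes: set[str],
    truthA: str = "A",
    truthB: str = "B",
) -> SwapAssessment:
    """Quantify barcode swapping in a two-species mixing experiment.

    ``assignments`` are ``(assigned_barcode_id, truth_species)`` pairs.
    ``rate_truthA_under_B`` is the fraction of reads assigned to group-B
    barcodes whose true origin is species A (and symmetrically). Under a
    uniform random-destination swap model the expected ratio of the two
    rates is ``|groupA| / |groupB|``: a swapped molecule from the large
    group has that many more target barcodes in it.
    """
    groupA_barcodes, groupB_barcodes = set(groupA_barcodes), set(groupB_barcodes)
    if not groupA_barcodes or not groupB_barcodes:
        raise ValueError("both barcode groups must be non-empty")
    if groupA_barcodes & groupB_barcodes:
        raise ValueError("barcode groups must be disjoint")
    n_under_A = n_under_B = swapped_A_under_B = swapped_B_under_A = 0
    for bc_id, truth in assignments:
        if bc_id in groupA_barcodes:
            n_under_A += 1
            if truth == truthB:
                swapped_B_under_A += 1
        elif bc_id in groupB_barcodes:
            n_under_B += 1
            if truth == truthA:
                swapped_A_under_B += 1
    flags = []
    if n_under_A == 0:
        flags.append("no reads assigned to group A; rate_truthB_under_A undefined")
    if n_under_B == 0:
        flags.append("no reads assigned to group B; rate_truthA_under_B undefined")
    return SwapAssessment(
        rate_truthA_under_B=swapped_A_under_B / n_under_B if n_under_B else math.nan,
        rate_truthB_under_A=swapped_B_under_A / n_under_A if n_under_A else math.nan,
        expected_ratio_uniform=len(groupA_barcodes) / len(groupB_barcodes),
        n_under_A=n_under_A,
        n_under_B=n_under_B,
        flags=flags,
    )


def multiplex_cost(n_samples: int, plex: int) -> int:
    """Number of reaction tubes needed to prepare ``n_samples`` at ``plex``-plex.

    Pooling before library prep turns N per-sample preparations into
    ceil(N / plex) one-pot reactions.
    """
    if n_samples < 1 or plex < 1:
        raise ValueError("n_samples and plex must be positive")
    return math.ceil(n_samples / plex)
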