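"""Structural-variant tier merging and kataegis detection.

SV calls from multiple callers and samples are clustered by breakpoint
proximity (single-linkage within a fixed tolerance, same type and strand
orientation) and filtered in two tiers: the high-confidence tier keeps
multi-sample clusters built from the trusted per-sample call subset
(somatic calls from the second caller, high-confidence calls from the
third), and the rescue tier keeps all-caller clusters that are both seen in
bulk and supported by multiple samples. Clusters touching low-mapping-
quality regions are discarded in both tiers.

Kataegis — localized hypermutation — is detected from highly confident
SNVs (>= 6 detecting samples, > 20 total supporting reads) as maximal runs
of >= 6 mutations with successive inter-mutation distances <= 1 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable

import numpy as np
import pandas as pd

SV_TYPES = ("DEL", "DUP", "INV", "TRA")
INTRA_TYPES = ("DEL", "DUP", "INV")


@dataclass
class SVCall:
    sample_id: str
    caller_id: str
    svtype: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    strand1: str = "+"
    strand2: str = "-"
    tier_flag: str = "none"  # somatic / high_confidence / none

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValueError("positions must be 1-based positive")
        if self.svtype in INTRA_TYPES and self.chrom1 != self.chrom2:
            raise ValueError(f"{self.svtype} must be intra-chromosomal")

    def normalized(self) -> "SVCall":
        """Canonical ordering: pos1 <= pos2 intra-chromosomal; chrom1 < chrom2 for TRA."""
        c = self
        if c.svtype in INTRA_TYPES and c.pos1 > c.pos2:
            c = replace(c, pos1=c.pos2, pos2=c.pos1,
                        strand1=c.strand2, strand2=c.strand1)
        if c.svtype == "TRA" and c.chrom1 > c.chrom2:
            c = replace(c, chrom1=c.chrom2, pos1=c.pos2, strand1=c.strand2,
                        chrom2=c.chrom1, pos2=c.pos1, strand2=c.strand1)
        return c

    @property
    def orientation(self) -> str:
        return self.strand1 + self.strand2


@dataclass
class SVCluster:
    members: list[SVCall]
    svtype: str
    orientation: str
    chrom1: str
    pos1: int            # median of member breakpoints
    chrom2: str
    pos2: int
    support_samples: set[str] = field(default_factory=set)
    in_bulk: bool = False
    tier: str | None = None


BULK_SAMPLE = "bulk"


def merge_sv(
    calls: Iterable[SVCall],
    tolerance_bp: int = 1000,
    bulk_sample: str = BULK_SAMPLE,
) -> list[SVCluster]:
    """Single-linkage clustering of SV calls by breakpoint proximity.

    Calls cluster only with calls of the same type, orientation and
    chromosome pair whose both breakpoints lie within ``tolerance_bp``.
    Cluster representatives are per-end medians; output is sorted by
    coordinates and independent of the input order.
    """
    normalized = sorted(
        (c.normalized() for c in calls),
        key=lambda c: (c.svtype, c.orientation, c.chrom1, c.chrom2,
                       c.pos1, c.pos2, c.sample_id, c.caller_id),
    )
    groups: dict[tuple, list[SVCall]] = {}
    for c in normalized:
        groups.setdefault((c.svtype, c.orientation, c.chrom1, c.chrom2), []).append(c)
    clusters: list[SVCluster] = []
    for (svtype, orientation, chrom1, chrom2), members in groups.items():
        n = len(members)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if members[j].pos1 - members[i].pos1 > tolerance_bp:
                    break  # sorted by pos1
                if abs(members[i].pos2 - members[j].pos2) <= tolerance_bp:
                    parent[find(i)] = find(j)
        by_root: dict[int, list[SVCall]] = {}
        for i in range(n):
            by_root.setdefault(find(i), []).append(members[i])
        for group in by_root.values():
            samples = {c.sample_id for c in group}
            clusters.append(SVCluster(
                members=group,
                svtype=svtype,
                orientation=orientation,
                chrom1=chrom1,
                pos1=int(median(c.pos1 for c in group)),
                chrom2=chrom2,
                pos2=int(median(c.pos2 for c in group)),
                support_samples=samples - {bulk_sample},
                in_bulk=bulk_sample in samples,
            ))
    clusters.sort(key=lambda cl: (cl.chrom1, cl.pos1, cl.chrom2, cl.pos2, cl.svtype))
    return clusters


def _in_regions(chrom: str, pos: int, regions: dict[str, np.ndarray]) -> bool:
    """Whether a 1-based position falls in any 0-based half-open interval."""
    iv = regions.get(chrom)
    if iv is None or len(iv) == 0:
        return False
    starts, ends = iv[:, 0], iv[:, 1]
    k = np.searchsorted(starts, pos - 1, side="right") - 1
    return bool(k >= 0 and pos - 1 < ends[k])


def prepare_regions(regions: Iterable[tuple[str, int, int]]) -> dict[str, np.ndarray]:
    """Index low-MQ BED intervals (chrom, start, end) for containment tests."""
    by_chrom: dict[str, list] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    return {c: np.array(sorted(iv)) for c, iv in by_chrom.items()}


# caller roles in the tier scheme; names follow the pipeline configuration
TRUSTED_SUBSET = {
    "manta": "somatic",
    "gridss": "high_confidence",
}


def tiered_sv_filter(
    sample_calls: Iterable[SVCall],
    bulk_calls: Iterable[SVCall],
    low_mq_regions: Iterable[tuple[str, int, int]] = (),
    min_samples: int = 2,
    tolerance_bp: int = 1000,
    trusted_subset: dict[str, str] | None = None,
    bulk_rule: str = "and",
) -> list[SVCluster]:
    """Two-tier consensus SV filtering.

    Tier *high*: per-sample trusted calls (by default somatic calls from
    manta plus high-confidence calls from gridss) are merged across samples
    and bulk, clusters overlapping low-MQ regions are removed, and clusters
    with >= ``min_samples`` supporting samples are kept.

    Tier *bulk_supported*: the union of all callers is merged and filtered
    the same way, but a cluster is kept only when it is present in bulk
    AND has >= ``min_samples`` supporting samples (``bulk_rule="or"``
    relaxes the conjunction).

    The result is the union, labelled by tier (high wins on overlap).
    """
    trusted = TRUSTED_SUBSET if trusted_subset is None else trusted_subset
    sample_calls = list(sample_calls)
    bulk_calls = [replace(c, sample_id=BULK_SAMPLE) for c in bulk_calls]
    for c in sample_calls + bulk_calls:
        if not c.caller_id:
            raise ValueError("caller annotation missing")
    regions = prepare_regions(low_mq_regions)

    def region_ok(cl: SVCluster) -> bool:
        return not (_in_regions(cl.chrom1, cl.pos1, regions)
                    or _in_regions(cl.chrom2, cl.pos2, regions))

    trusted_sample = [
        c for c in sample_calls if trusted.get(c.caller_id) == c.tier_flag
    ]
    tier_high = [
        cl for cl in merge_sv(trusted_sample + bulk_calls, tolerance_bp)
        if region_ok(cl) and len(cl.support_samples) >= min_samples
    ]
    all_merged = merge_sv(sample_calls + bulk_calls, tolerance_bp)
    if bulk_rule == "and":
        tier_bulk = [
            cl for cl in all_merged
            if region_ok(cl) and cl.in_bulk and len(cl.support_samples) >= min_samples
        ]
    elif bulk_rule == "or":
        tier_bulk = [
            cl for cl in all_merged
            if region_ok(cl) and (cl.in_bulk or len(cl.support_samples) >= min_samples)
        ]
    else:
        raise ValueError("bulk_rule must be 'and' or 'or'")

    final: list[SVCluster] = []

    def already_present(cl: SVCluster) -> bool:
        return any(
            f.svtype == cl.svtype and f.orientation == cl.orientation
            and f.chrom1 == cl.chrom1 and f.chrom2 == cl.chrom2
            and abs(f.pos1 - cl.pos1) <= tolerance_bp
            and abs(f.pos2 - cl.pos2) <= tolerance_bp
            for f in final
        )

    for cl, tier in [(c, "high") for c in tier_high] + [
        (c, "bulk_supported") for c in tier_bulk
    ]:
        if already_present(cl):
            continue
        final.append(replace(cl, tier=tier))
    final.sort(key=lambda cl: (cl.chrom1, cl.pos1, cl.chrom2, cl.pos2, cl.svtype))
    return final


def kataegis_filter_snvs(
    detections: pd.DataFrame,
    min_samples: int = 6,
    min_total_reads: int = 20,
) -> pd.DataFrame:
    """Highly confident SNVs for kataegis calling.

    ``detections`` has one row per (sample, site) detection with columns
    sample_id, chrom, pos, supporting_reads. A site is kept iff it is
    detected in >= ``min_samples`` distinct samples and the summed
    supporting reads strictly exceed ``min_total_reads``.
    """
    need = {"sample_id", "chrom", "pos", "supporting_reads"}
    if not need <= set(detections.columns):
        raise ValueError(f"detections must have columns {sorted(need)}")
    if detections.empty:
        return pd.DataFrame(columns=["chrom", "pos"])
    grouped = detections.groupby(["chrom", "pos"]).agg(
        n_samples=("sample_id", "nunique"),
        total_reads=("supporting_reads", "sum"),
    )
    kept = grouped[
        (grouped["n_samples"] >= min_samples)
        & (grouped["total_reads"] > min_total_reads)
    ]
    return kept.reset_index()[["chrom", "pos"]].sort_values(
        ["chrom", "pos"]).reset_index(drop=True)


@dataclass
class KataegisEvent:
    chrom: str
    start: int
    end: int
    n_mutations: int
    mean_imd: float


def _check_sorted_dedup(positions: np.ndarray, chrom: str) -> None:
    if len(positions) > 1:
        d = np.diff(positions)
        if (d < 0).any():
            raise ValueError(f"positions on {chrom} are not sorted")
        if (d == 0).any():
            raise ValueError(f"duplicate positions on {chrom}; deduplicate first")


def detect_kataegis(
    positions: dict[str, np.ndarray],
    min_mutations: int = 6,
    max_imd_bp: int = 1000,
) -> list[KataegisEvent]:
    """Maximal runs of closely spaced mutations.

    For each chromosome's sorted, deduplicated 1-based positions, report
    every maximal run of >= ``min_mutations`` mutations whose successive
    inter-mutation distances are all <= ``max_imd_bp``.
    """
    events = []
    for chrom in sorted(positions):
        pos = np.asarray(positions[chrom], dtype=np.int64)
        _check_sorted_dedup(pos, chrom)
        if len(pos) < min_mutations:
            continue
        gaps = np.diff(pos)
        run_start = 0
        for i, g in enumerate(gaps):
            if g > max_imd_bp:
                if i + 1 - run_start >= min_mutations:
                    events.append(_make_event(chrom, pos[run_start:i + 1]))
                run_start = i + 1
        if len(pos) - run_start >= min_mutations:
            events.append(_make_event(chrom, pos[run_start:]))
    return events


def _make_event(chrom: str, run: np.ndarray) -> KataegisEvent:
    return KataegisEvent(
        chrom=chrom,
        start=int(run[0]),
        end=int(run[-1]),
        n_mutations=len(run),
        mean_imd=float(np.diff(run).mean()),
    )


def rainfall(positions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Rainfall-plot coordinates: each mutation's distance to the previous one.

    The first mutation of each chromosome has no predecessor and is
    omitted. Duplicate or unsorted positions are an error.
    """
    rows = []
    for chrom in sorted(positions):
        pos = np.asarray(positions[chrom], dtype=np.int64)
        _check_sorted_dedup(pos, chrom)
        for p, d in zip(pos[1:], np.diff(pos)):
            rows.append({"chrom": chrom, "pos": int(p), "imd": int(d)})
    return pd.DataFrame(rows, columns=["chrom", "pos", "imd"])
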