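"""Consensus somatic SNV calling across callers and samples.

Single-cell whole-genome-amplification data are noisy enough that no single
variant caller is trusted: a site becomes a *confident* somatic site only
when at least ``min_callers`` distinct callers support it in each of at
least ``min_samples`` samples. Per sample, a confident site is then
genotyped as called if any caller reported it, or rescued when its
alternate-allele pileup count is significantly larger than the largest
other non-reference base count (one-sided Fisher exact test, p < 1e-3 by
default) — sequencing errors hit all three alternate bases at similar
rates, real alleles only one. Base counts are expected to be pre-filtered
to reads with mapping and base quality > 30.

The module also hosts the amplification quality estimators: allelic-dropout
rate at confident heterozygous SNPs (coverage >= 10), per-base
false-positive rate at confident homozygous sites (bulk coverage >= 20),
germline detection sensitivity, and the coincident false-positive
probability motivating the two-sample rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = ("A", "C", "G", "T")
CALL_COLUMNS = ["sample_id", "caller_id", "chrom", "pos", "ref", "alt"]
PILEUP_COLUMNS = ["sample_id", "chrom", "pos", "ref", "nA", "nC", "nG", "nT"]

Site = tuple[str, int, str, str]  # (chrom, pos, ref, alt); pos 1-based

CALLED = "called"
NOT_CALLED = "not_called"
LOW_COVERAGE = "low_coverage"


def _as_call_frame(calls) -> pd.DataFrame:
    df = pd.DataFrame(calls, columns=CALL_COLUMNS) if not isinstance(calls, pd.DataFrame) else calls
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    return df


def consensus_sites(
    calls,
    min_callers: int = 2,
    min_samples: int = 2,
) -> list[Site]:
    """Confident somatic sites: >= min_callers callers in >= min_samples samples.

    ``calls`` is a table (or iterable of rows) with columns
    sample_id, caller_id, chrom, pos, ref, alt. Output sorted by (chrom, pos).
    """
    df = _as_call_frame(calls)
    if df.empty:
        return []
    site_cols = ["chrom", "pos", "ref", "alt"]
    per_sample = (
        df.drop_duplicates(site_cols + ["sample_id", "caller_id"])
        .groupby(site_cols + ["sample_id"])["caller_id"]
        .nunique()
    )
    qualified = per_sample[per_sample >= min_callers]
    per_site = qualified.groupby(site_cols).size()
    kept = per_site[per_site >= min_samples].index
    return sorted(
        [(c, int(p), r, a) for c, p, r, a in kept], key=lambda s: (s[0], s[1], s[2], s[3])
    )


def fisher_rescue(
    counts: dict[str, int],
    ref: str,
    alt: str,
    p_threshold: float = 1e-3,
) -> tuple[float, bool]:
    """Rescue a missed call from pileup base counts.

    One-sided Fisher exact test that the alternate-allele count exceeds the
    *largest* count among the two other non-reference bases (the most
    conservative pairwise contrast with the sequencing-error background):

        [[n_alt,         n_err_max        ],
         [depth - n_alt,  depth - n_err_max]]

    Returns (p_value, called) with called iff p < ``p_threshold``.
    """
    if ref == alt:
        raise ValueError("alt must differ from ref")
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"ref/alt must be one of {BASES}")
    depth = sum(int(counts.get(b, 0)) for b in BASES)
    if depth <= 0:
        raise ValueError("zero-depth pileup")
    n_alt = int(counts.get(alt, 0))
    others = [int(counts.get(b, 0)) for b in BASES if b not in (ref, alt)]
    n_err = max(others)
    table = [[n_alt, n_err], [depth - n_alt, depth - n_err]]
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    return p, p < p_threshold


@dataclass
class ConsensusCallSet:
    """Per-sample genotypes at cross-sample confident SNV sites."""

    sites: list[Site]
    samples: list[str]
    genotypes: pd.DataFrame            # samples x sites, values in {called, not_called, low_coverage}
    caller_support: pd.DataFrame       # samples x sites, int
    fisher_p: pd.DataFrame             # samples x sites, float (NaN where untested)
    coverage: pd.DataFrame             # samples x sites, int

    def called_sites(self, sample: str) -> set[Site]:
        row = self.genotypes.loc[sample]
        return {self.sites[i] for i, v in enumerate(row) if v == CALLED}


def _pileup_lookup(pileups) -> dict[tuple[str, str, int], dict[str, int]]:
    df = pd.DataFrame(pileups, columns=PILEUP_COLUMNS) if not isinstance(pileups, pd.DataFrame) else pileups
    out = {}
    for row in df.itertuples(index=False):
        out[(row.sample_id, row.chrom, int(row.pos))] = {
            "A": int(row.nA), "C": int(row.nC), "G": int(row.nG), "T": int(row.nT),
        }
    return out


def genotype_samples(
    sites: list[Site],
    calls,
    pileups,
    p_threshold: float = 1e-3,
    min_rescue_depth: int = 1,
    low_cov_floor: int = 5,
    samples: list[str] | None = None,
) -> ConsensusCallSet:
    """Genotype every sample at every confident site.

    A sample is *called* at a site if any of the callers reported it there
    (rule 1) or the Fisher rescue on its pileup is significant (rule 2).
    Otherwise the site is *low_coverage* when the pileup depth is below
    ``low_cov_floor`` (or missing), else *not_called*.
    """
    df = _as_call_frame(calls)
    if samples is None:
        samples = sorted(df["sample_id"].unique())
    lookup = _pileup_lookup(pileups)
    support_per = (
        df.groupby(["sample_id", "chrom", "pos", "ref", "alt"])["caller_id"].nunique()
        if not df.empty else pd.Series(dtype=int)
    )
    n_sites = len(sites)
    geno = pd.DataFrame(NOT_CALLED, index=samples, columns=range(n_sites))
    supp = pd.DataFrame(0, index=samples, columns=range(n_sites))
    fishp = pd.DataFrame(np.nan, index=samples, columns=range(n_sites))
    cov = pd.DataFrame(0, index=samples, columns=range(n_sites))
    for j, (chrom, pos, ref, alt) in enumerate(sites):
        for s in samples:
            counts = lookup.get((s, chrom, pos))
            depth = sum(counts.values()) if counts else 0
            cov.loc[s, j] = depth
            n_support = int(support_per.get((s, chrom, pos, ref, alt), 0))
            supp.loc[s, j] = n_support
            if n_support >= 1:
                geno.loc[s, j] = CALLED
                continue
            if counts and depth >= min_rescue_depth:
                p, called = fisher_rescue(counts, ref, alt, p_threshold)
                fishp.loc[s, j] = p
                if called:
                    geno.loc[s, j] = CALLED
                    continue
            if depth < low_cov_floor:
                geno.loc[s, j] = LOW_COVERAGE
    return ConsensusCallSet(
        sites=list(sites), samples=list(samples), genotypes=geno,
        caller_support=supp, fisher_p=fishp, coverage=cov,
    )


@dataclass
class RateEstimate:
    rate: float
    n_assessed: int
    n_events: int
    flags: list[str] = field(default_factory=list)


def ado_rate(
    het_sites: pd.DataFrame,
    pileups,
    min_cov: int = 10,
) -> RateEstimate:
    """Allelic-dropout rate at confident heterozygous SNPs.

    ``het_sites`` needs columns chrom, pos, allele_a, allele_b (the two
    alleles confirmed heterozygous in bulk, in copy-number-2 regions).
    Sites are assessed when the single-cell pileup depth is >= ``min_cov``;
    a dropout is exactly one of the two alleles having zero reads.
    """
    lookup = _pileup_lookup(pileups)
    by_pos: dict[tuple[str, int], dict[str, int]] = {}
    for (sample, chrom, pos), counts in lookup.items():
        by_pos[(chrom, pos)] = counts  # one sample's pileup per call
    n_assessed = n_dropout = 0
    for row in het_sites.itertuples(index=False):
        counts = by_pos.get((row.chrom, int(row.pos)))
        if counts is None:
            continue
        if sum(counts.values()) < min_cov:
            continue
        n_assessed += 1
        a, b = counts.get(row.allele_a, 0), counts.get(row.allele_b, 0)
        if (a == 0) != (b == 0):
            n_dropout += 1
    flags = []
    if n_assessed == 0:
        flags.append("no heterozygous sites with sufficient coverage; rate undefined")
        return RateEstimate(float("nan"), 0, 0, flags)
    return RateEstimate(n_dropout / n_assessed, n_assessed, n_dropout, flags)


def fpr_estimate(
    hom_sites: pd.DataFrame,
    somatic_calls: set[tuple[str, int]],
    min_bulk_cov: int = 20,
) -> RateEstimate:
    """Per-base false-positive mutation rate at confident homozygous sites.

    ``hom_sites`` carries the bulk base counts (columns chrom, pos, nA, nC,
    nG, nT). A site is confidently homozygous when its bulk depth is
    >= ``min_bulk_cov`` and exactly one allele is observed. The FPR is the
    fraction of those sites at which the single-cell pipeline emitted a
    somatic call (positions given as a set of (chrom, pos)).
    """
    counts = hom_sites[["nA", "nC", "nG", "nT"]].to_numpy(dtype=np.int64)
    depth = counts.sum(axis=1)
    confident = (depth >= min_bulk_cov) & ((counts > 0).sum(axis=1) == 1)
    n_sites = int(confident.sum())
    if n_sites == 0:
        return RateEstimate(float("nan"), 0, 0,
                            ["no confident homozygous sites; rate undefined"])
    conf = hom_sites.loc[confident, ["chrom", "pos"]]
    n_fp = sum(
        (chrom, int(pos)) in somatic_calls
        for chrom, pos in conf.itertuples(index=False)
    )
    return RateEstimate(n_fp / n_sites, n_sites, n_fp, [])


def germline_sensitivity(
    detected: set[Site],
    truth: set[Site],
    coverage: dict[Site, int] | None = None,
    min_cov: int = 5,
) -> float:
    """Fraction of bulk germline variants recovered in a single sample.

    When per-site coverage is supplied, the denominator is restricted to
    truth sites the sample could have assessed (depth >= ``min_cov``).
    """
    if not truth:
        raise ValueError("truth germline set is empty")
    assessable = truth
    if coverage is not None:
        assessable = {s for s in truth if coverage.get(s, 0) >= min_cov}
        if not assessable:
            raise ValueError("no assessable truth sites at the coverage floor")
    return len(detected & assessable) / len(assessable)


def coincident_fp_probability(fpr_per_base: float, n_samples: int = 2) -> float:
    """Probability of the same false positive arising at one site in n samples.

    Under independent per-sample errors this is fpr**n_samples — the reason
    requiring a variant in two samples suppresses amplification artifacts.
    """
    if not 0 <= fpr_per_base < 1:
        raise ValueError("fpr must be in [0, 1)")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    return fpr_per_base ** n_samples
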