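"""Copy-number analysis from binned read depth.

The read-depth pipeline for sparse single-cell whole-genome-amplification
data: the genome is cut into variable-size bins carrying equal expected
numbers of uniquely aligned reads (so mappability deserts widen their bins),
per-bin counts are GC-corrected with a robust LOWESS fit and scaled to a
near-diploid mean of 2, copy-number segments are found by circular binary
segmentation (CBS) and consolidated with a MergeLevels-style rank test, and
amplification uniformity is summarized by the Lorenz curve and its area.

Bins use 0-based half-open coordinates (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

WINDOW_COLUMNS = ["chrom", "start", "end", "gc", "weight"]


@dataclass
class GenomeModel:
    """Chromosome sizes plus a fixed-window GC / mappability-weight track.

    ``windows`` must tile each chromosome with non-overlapping, sorted,
    0-based half-open intervals carrying a GC fraction and a non-negative
    weight (expected uniquely-aligned read density).
    """

    chromosomes: list[tuple[str, int]]
    windows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(WINDOW_COLUMNS) - set(self.windows.columns)
        if missing:
            raise ValueError(f"window table missing columns: {sorted(missing)}")
        w = self.windows
        if (w["weight"] < 0).any():
            raise ValueError("window weights must be non-negative")
        if ((w["gc"] < 0) | (w["gc"] > 1)).any():
            raise ValueError("window GC must lie in [0, 1]")
        for chrom, grp in w.groupby("chrom", sort=False):
            if not (grp["start"].values[1:] == grp["end"].values[:-1]).all():
                raise ValueError(f"windows do not tile chromosome {chrom}")


@dataclass
class BinScheme:
    """Variable-size bins plus the window->bin assignment used to build them."""

    bins: pd.DataFrame            # chrom, start, end, gc, weight
    window_bin: np.ndarray        # per input window, index of its bin

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def aggregate_window_values(self, values: np.ndarray) -> np.ndarray:
        """Sum a per-window quantity (e.g. read counts) into bins."""
        values = np.asarray(values, dtype=float)
        if values.shape[0] != self.window_bin.shape[0]:
            raise ValueError("values must have one entry per window")
        out = np.zeros(self.n_bins)
        np.add.at(out, self.window_bin, values)
        return out


@dataclass
class SegmentationParams:
    alpha: float = 1e-10
    nperm: int = 1000
    min_width: int = 5
    undo_sd: float = 0.8
    ansari_sign: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.nperm < 100:
            raise ValueError("nperm must be >= 100")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


@dataclass
class Segment:
    """A run of bins [start, end] (inclusive) sharing one copy-number level."""

    start: int
    end: int
    mean: float
    state: str | None = None

    @property
    def n_bins(self) -> int:
        return self.end - self.start + 1


def make_variable_bins(genome: GenomeModel, n_bins: int) -> BinScheme:
    """Partition genome windows into ~``n_bins`` equal-weight bins.

    Per chromosome, the bin count is allocated proportionally to chromosome
    weight and boundaries are placed at equally spaced quantiles of the
    cumulative weight, so each bin carries the global target weight to
    within one window's weight. Bins never cross chromosomes.
    """
    win = genome.windows.reset_index(drop=True)
    total_weight = win["weight"].sum()
    if total_weight <= 0:
        raise ValueError("total window weight must be positive")
    if n_bins > len(win):
        raise ValueError("n_bins exceeds number of windows")
    bin_rows = []
    window_bin = np.empty(len(win), dtype=int)
    next_bin = 0
    for chrom, grp in win.groupby("chrom", sort=False):
        w = grp["weight"].to_numpy(dtype=float)
        chrom_weight = w.sum()
        m = max(1, int(round(n_bins * chrom_weight / total_weight)))
        m = min(m, len(grp))
        cum = np.cumsum(w)
        # boundary after the window whose cumulative weight crosses k*W/m
        thresholds = chrom_weight * np.arange(1, m) / m
        cut = np.searchsorted(cum, thresholds, side="left") + 1
        edges = np.concatenate([[0], np.unique(cut), [len(grp)]])
        for lo, hi in zip(edges[:-1], edges[1:]):
            sub = grp.iloc[lo:hi]
            bin_rows.append({
                "chrom": chrom,
                "start": int(sub["start"].iloc[0]),
                "end": int(sub["end"].iloc[-1]),
                "gc": float(sub["gc"].mean()),
                "weight": float(sub["weight"].sum()),
            })
            window_bin[grp.index[lo:hi]] = next_bin
            next_bin += 1
    return BinScheme(bins=pd.DataFrame(bin_rows), window_bin=window_bin)


def gc_normalize(
    counts: np.ndarray,
    bins: BinScheme | pd.DataFrame,
    lowess_frac: float = 0.3,
) -> np.ndarray:
    """GC-correct per-bin counts and scale to a mean of 2.

    A robust LOWESS regression of count on GC estimates the expected count
    at each bin's GC; the ratio count / fit removes the GC trend and the
    result is rescaled so the genome-wide mean is exactly 2 (near-diploid
    assumption).
    """
    counts = np.asarray(counts, dtype=float)
    table = bins.bins if isinstance(bins, BinScheme) else bins
    if len(counts) != len(table):
        raise ValueError("counts length must equal number of bins")
    if counts.sum() <= 0:
        raise ValueError("all counts are zero")
    gc = table["gc"].to_numpy(dtype=float)
    fit = lowess(counts, gc, frac=lowess_frac, it=3, xvals=gc)
    floor = 0.01 * counts.mean()
    fit = np.maximum(fit, floor)
    ratios = counts / fit
    return ratios * (2.0 / ratios.mean())


def _noise_sd(x: np.ndarray) -> float:
    """Robust noise scale from median absolute successive difference."""
    if len(x) < 2:
        return 0.0
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    sd = 1.4826 * mad / np.sqrt(2)
    if sd <= 0:
        sd = float(np.std(x)) or 1e-12
    return float(sd)


def _max_arc_statistic(
    x: np.ndarray, sd: float, min_width: int
) -> tuple[float, int, int, int]:
    """Max two-sample t-like statistic over arcs x[i:j].

    Candidate arcs have length >= min_width and leave every resulting
    segment at least min_width wide (flank lengths are 0 or >= min_width).
    Returns (|Z|max, i, j, n_arcs_tested).
    """
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    total = s[-1]
    best_z, best_i, best_j = -1.0, 0, n
    n_tested = 0
    for i in range(0, n - min_width + 1):
        if i != 0 and i < min_width:
            continue
        j_lo = i + min_width
        js = np.arange(j_lo, n + 1)
        # right flank must be empty or >= min_width
        js = js[(js == n) | (js <= n - min_width)]
        k = js - i
        valid = k < n  # a full-length arc is no split
        js, k = js[valid], k[valid]
        if len(js) == 0:
            continue
        arc = s[js] - s[i]
        rest = total - arc
        z = np.abs(arc / k - rest / (n - k)) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
        n_tested += len(js)
        m = int(np.argmax(z))
        if z[m] > best_z:
            best_z, best_i, best_j = float(z[m]), i, int(js[m])
    return best_z, best_i, best_j, n_tested


def _split_p_value(
    x: np.ndarray, z_obs: float, n_tested: int, params: SegmentationParams,
    sd: float, rng: np.random.Generator,
) -> float:
    """Hybrid significance for the best arc split.

    Permutation p-value when ``alpha`` is resolvable with ``nperm`` shuffles
    (alpha >= 1/(nperm+1)); otherwise a Bonferroni-style Gaussian tail bound
    over the arcs tested, which is the only way to reach thresholds like
    1e-10.
    """
    if params.alpha >= 1.0 / (params.nperm + 1):
        exceed = 0
        limit = params.alpha * (params.nperm + 1)
        for _ in range(params.nperm):
            perm = rng.permutation(x)
            z_perm, _, _, _ = _max_arc_statistic(perm, sd, params.min_width)
            if z_perm >= z_obs:
                exceed += 1
                if exceed > limit:  # cannot become significant; stop early
                    break
        return (1 + exceed) / (params.nperm + 1)
    return float(min(1.0, n_tested * 2.0 * stats.norm.sf(z_obs)))


def cbs_segment(
    ratios: np.ndarray,
    params: SegmentationParams | None = None,
    seed: int | None = 0,
) -> list[Segment]:
    """Circular binary segmentation of an ordered ratio vector.

    Recursively finds the arc maximizing the two-sample statistic against
    its complement, splits when significant at ``alpha`` (hybrid
    permutation / Gaussian-tail p-value), enforces ``min_width``, and
    finally undoes splits whose adjacent segment means differ by less than
    ``undo_sd`` times the robust noise SD.
    """
    params = params or SegmentationParams()
    x = np.asarray(ratios, dtype=float)
    n = len(x)
    if n < 2 * params.min_width:
        warnings.warn("too few bins to segment; returning a single segment")
        return [Segment(0, n - 1, float(x.mean()))]
    sd = _noise_sd(x)
    rng = np.random.default_rng(seed)

    boundaries = {0, n}

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if len(seg) < 2 * params.min_width:
            return
        z, i, j, n_tested = _max_arc_statistic(seg, sd, params.min_width)
        if z < 0:
            return
        p = _split_p_value(seg, z, n_tested, params, sd, rng)
        if p >= params.alpha:
            return
        cuts = [c for c in (lo + i, lo + j) if lo < c < hi]
        if not cuts:
            return
        boundaries.update(cuts)
        pieces = sorted({lo, hi, *cuts})
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    recurse(0, n)
    edges = sorted(boundaries)
    segments = [
        Segment(a, b - 1, float(x[a:b].mean())) for a, b in zip(edges[:-1], edges[1:])
    ]
    return _undo_splits(segments, params.undo_sd * sd)


def _undo_splits(segments: list[Segment], threshold: float) -> list[Segment]:
    """Merge adjacent segments whose means differ by less than ``threshold``."""
    segs = list(segments)
    while len(segs) > 1:
        diffs = [abs(a.mean - b.mean) for a, b in zip(segs[:-1], segs[1:])]
        k = int(np.argmin(diffs))
        if diffs[k] >= threshold:
            break
        a, b = segs[k], segs[k + 1]
        merged_mean = (a.mean * a.n_bins + b.mean * b.n_bins) / (a.n_bins + b.n_bins)
        segs[k:k + 2] = [Segment(a.start, b.end, merged_mean)]
    return segs


def merge_levels(
    segments: list[Segment],
    ratios: np.ndarray,
    ansari_sign: float = 0.1,
) -> list[Segment]:
    """MergeLevels-style consolidation of segment levels.

    Repeatedly takes the two copy-number levels (not necessarily adjacent
    segments) with the closest means and compares their bin-value
    distributions with a Wilcoxon rank-sum test; if p > ``ansari_sign`` the
    levels are pooled (all member segments adopt the pooled mean). Stops
    when the closest pair differs significantly.
    """
    x = np.asarray(ratios, dtype=float)
    if not segments:
        return []
    # level = group of segments sharing a mean; start with one per segment
    levels: list[dict] = [
        {"segments": [k], "values": x[s.start:s.end + 1]}
        for k, s in enumerate(segments)
    ]
    while len(levels) > 1:
        means = np.array([lv["values"].mean() for lv in levels])
        order = np.argsort(means)
        gaps = np.diff(means[order])
        g = int(np.argmin(gaps))
        a, b = order[g], order[g + 1]
        va, vb = levels[a]["values"], levels[b]["values"]
        if np.array_equal(va, vb):
            p = 1.0
        else:
            p = stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue
        if p <= ansari_sign:
            break
        merged = {
            "segments": levels[a]["segments"] + levels[b]["segments"],
            "values": np.concatenate([va, vb]),
        }
        levels = [lv for k, lv in enumerate(levels) if k not in (a, b)] + [merged]
    out = [replace(s) for s in segments]
    for lv in levels:
        pooled = float(lv["values"].mean())
        for k in lv["segments"]:
            out[k] = replace(out[k], mean=pooled)
    return out


def call_states(
    segments: list[Segment], neutral_band: float = 0.3
) -> list[Segment]:
    """Label segments loss/neutral/gain around a diploid level of 2."""
    out = []
    for s in segments:
        if s.mean < 2 - neutral_band:
            state = "loss"
        elif s.mean > 2 + neutral_band:
            state = "gain"
        else:
            state = "neutral"
        out.append(replace(s, state=state))
    return out


def states_per_bin(segments: list[Segment], n_bins: int) -> np.ndarray:
    """Expand segment states to one label per bin."""
    out = np.empty(n_bins, dtype=object)
    for s in segments:
        if s.state is None:
            raise ValueError("segments must be state-called first")
        out[s.start:s.end + 1] = s.state
    if (out == None).any():  # noqa: E711 - object array
        raise ValueError("segments do not cover all bins")
    return out


def log2_relative(ratios: np.ndarray) -> np.ndarray:
    """Heatmap transform: log2 of copy ratio relative to the diploid mean 2."""
    r = np.asarray(ratios, dtype=float)
    return np.log2(np.maximum(r, 1e-6) / 2.0)


def lorenz_auc(counts: np.ndarray) -> tuple[np.ndarray, float]:
    """Lorenz curve and its area for per-bin read counts.

    Bins are sorted ascending by count; the curve is cumulative read
    fraction vs cumulative bin fraction. Perfectly uniform coverage gives
    the diagonal and AUC = 0.5; skewed amplification pushes the curve down
    and the AUC toward 0.
    """
    c = np.sort(np.asarray(counts, dtype=float))
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    n = len(c)
    xs = np.arange(n + 1) / n
    ys = np.concatenate([[0.0], np.cumsum(c) / total])
    auc = float(np.trapezoid(ys, xs))
    return np.column_stack([xs, ys]), auc


@dataclass
class ConcordanceResult:
    sensitivity: float
    specificity: float
    n_aberrant_bulk: int
    n_neutral_bulk: int
    flags: list[str] = field(default_factory=list)


def cna_concordance(
    sample_states: np.ndarray, bulk_states: np.ndarray
) -> ConcordanceResult:
    """Per-bin copy-state agreement against a bulk truth profile.

    Sensitivity: fraction of bulk-aberrant bins (gain/loss) whose state the
    sample reproduces exactly. Specificity: fraction of bulk-neutral bins
    the sample also calls neutral.
    """
    sample_states = np.asarray(sample_states, dtype=object)
    bulk_states = np.asarray(bulk_states, dtype=object)
    if sample_states.shape != bulk_states.shape:
        raise ValueError("state vectors must have equal length")
    aberrant = (bulk_states == "gain") | (bulk_states == "loss")
    neutral = bulk_states == "neutral"
    flags = []
    if aberrant.sum() == 0:
        flags.append("no aberrant bins in bulk; sensitivity undefined")
        sens = float("nan")
    else:
        sens = float((sample_states[aberrant] == bulk_states[aberrant]).mean())
    if neutral.sum() == 0:
        flags.append("no neutral bins in bulk; specificity undefined")
        spec = float("nan")
    else:
        spec = float((sample_states[neutral] == "neutral").mean())
    return ConcordanceResult(
        sensitivity=sens,
        specificity=spec,
        n_aberrant_bulk=int(aberrant.sum()),
        n_neutral_bulk=int(neutral.sum()),
        flags=flags,
    )
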