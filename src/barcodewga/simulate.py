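"""Synthetic barcoded-amplification sequencing data.

Generates every input the pipeline consumes — barcoded read pairs, per-bin
read counts, per-site pileups, per-caller variant tables, SV call tables
and microniche coordinates — with the statistical structure the analysis
assumes, plus the ground truth needed to score recovery:

* a small genome (two 10-Mb chromosomes by default, 2-kb windows) with a
  smooth autocorrelated GC track and a mappability weight track;
* a fixed binary clonal genealogy of 4 subclones x 3 microniches with
  truncal, clade-shared, subclone-private and sample-private SNVs, plus
  subclone copy-number events, SVs and a truncal kataegis cluster;
* amplification artefacts: barcode-specific efficiency variation
  (CV ~ 0.30), rare barcode swaps, lognormal per-bin amplification noise
  (overdispersion sigma ~ 0.3), allelic dropout (~ 0.1-0.2) and per-base
  sequencing errors (~ 1e-5);
* three pseudo-callers with distinct sensitivity / false-positive
  profiles standing in for the independent variant callers.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .barcodes import BarcodeSet
from .cna import GenomeModel, BinScheme
from .demux import ReadPair
from .svkat import SVCall

BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    window_size: int = 2_000
    gc_mean: float = 0.45
    gc_sd: float = 0.05
    gc_smooth_windows: int = 50        # autocorrelation scale of the GC track
    weight_low: float = 0.7            # mappability weight range
    weight_high: float = 1.3

    @property
    def chromosomes(self) -> list[tuple[str, int]]:
        return [(f"chr{i + 1}", self.chrom_length) for i in range(self.n_chromosomes)]


@dataclass
class CloneConfig:
    n_subclones: int = 4
    samples_per_subclone: int = 3
    n_truncal: int = 100
    n_clade: int = 30                  # shared by pairs of subclones
    n_subclone_private: int = 50
    n_within_subclone: int = 15        # shared by a sample pair inside a subclone
    n_sample_private: int = 10


@dataclass
class SequencingConfig:
    cna_depth: int = 1_000_000         # reads for the copy-number track
    per_base_error: float = 1e-5
    ado: float = 0.15                  # P(one allele lost at a site)
    mda_sigma: float = 0.3             # lognormal per-bin amplification noise
    site_depth_mean: float = 30.0      # mean pileup depth at assessed sites


@dataclass
class BarcodingConfig:
    efficiency_cv: float = 0.30
    swap_rate: float = 0.0
    sub_rate: float = 0.001            # per-base substitution in the barcode
    read_len: int = 50


@dataclass
class CallerSpec:
    name: str
    sensitivity: float
    fpr: float = 1e-5

    def __post_init__(self) -> None:
        if not 0 <= self.sensitivity <= 1 or not 0 <= self.fpr <= 1:
            raise ValueError("sensitivity and fpr must be in [0, 1]")


DEFAULT_CALLERS = (
    CallerSpec("gatk", 0.80, 1e-5),
    CallerSpec("varscan", 0.85, 1e-5),
    CallerSpec("mutect", 0.90, 1e-5),
)


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    clones: CloneConfig = field(default_factory=CloneConfig)
    sequencing: SequencingConfig = field(default_factory=SequencingConfig)
    barcoding: BarcodingConfig = field(default_factory=BarcodingConfig)
    callers: tuple[CallerSpec, ...] = DEFAULT_CALLERS
    n_bins: int = 500
    kataegis_size: int = 8
    kataegis_spacing: int = 300

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# genome and clone structure
# ---------------------------------------------------------------------------

def make_genome(cfg: GenomeConfig, rng: np.random.Generator) -> GenomeModel:
    """Windowed genome with smooth GC and random mappability weights."""
    rows = []
    for chrom, length in cfg.chromosomes:
        n_win = length // cfg.window_size
        raw = rng.normal(size=n_win)
        kernel = np.ones(cfg.gc_smooth_windows) / cfg.gc_smooth_windows
        smooth = np.convolve(raw, kernel, mode="same")
        smooth = (smooth - smooth.mean()) / (smooth.std() or 1.0)
        gc = np.clip(cfg.gc_mean + cfg.gc_sd * smooth, 0.2, 0.8)
        weight = rng.uniform(cfg.weight_low, cfg.weight_high, size=n_win)
        starts = np.arange(n_win) * cfg.window_size
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + cfg.window_size,
            "gc": gc, "weight": weight,
        }))
    return GenomeModel(chromosomes=list(cfg.chromosomes),
                       windows=pd.concat(rows, ignore_index=True))


@dataclass
class CloneTree:
    """Fixed binary genealogy: samples, subclone labels, per-edge mutations."""

    samples: list[str]
    subclone_of: dict[str, str]
    edge_mutations: dict[str, list]    # edge name -> list of Site
    carriers: dict[str, list[str]]     # edge name -> samples below the edge
    newick: str                        # truth topology incl. the diploid root

    def sample_sites(self, sample: str) -> set:
        return {
            site for edge, sites in self.edge_mutations.items()
            for site in sites if sample in self.carriers[edge]
        }

    @property
    def truncal_sites(self) -> list:
        return self.edge_mutations["truncal"]


def _draw_sites(n: int, genome_cfg: GenomeConfig, rng: np.random.Generator,
                used: set) -> list:
    """Unique (chrom, pos, ref, alt) sites, 1-based, avoiding ``used``."""
    sites = []
    while len(sites) < n:
        chrom = f"chr{rng.integers(genome_cfg.n_chromosomes) + 1}"
        pos = int(rng.integers(1, genome_cfg.chrom_length + 1))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append((chrom, pos, str(BASES[ref]), str(BASES[alt])))
    return sites


def make_clone_tree(cfg: CloneConfig, genome_cfg: GenomeConfig,
                    rng: np.random.Generator) -> CloneTree:
    """Binary genealogy with mutations on every edge.

    Subclones form a balanced hierarchy ((c1,c2),(c3,c4)); inside each
    subclone of three samples one pair shares an extra internal edge, so
    the full genealogy is binary and recoverable from distances.
    """
    if cfg.n_subclones != 4 or cfg.samples_per_subclone != 3:
        raise ValueError("the default genealogy is fixed at 4 subclones x 3 samples")
    samples = [f"s{i + 1:02d}" for i in range(12)]
    subclones = [f"c{k + 1}" for k in range(4)]
    subclone_of = {s: subclones[i // 3] for i, s in enumerate(samples)}
    used: set = set()
    edge_mutations: dict[str, list] = {}
    carriers: dict[str, list[str]] = {}

    def add_edge(name: str, members: list[str], n_mut: int) -> None:
        edge_mutations[name] = _draw_sites(n_mut, genome_cfg, rng, used)
        carriers[name] = members

    add_edge("truncal", samples, cfg.n_truncal)
    add_edge("clade_c1c2", samples[0:6], cfg.n_clade)
    add_edge("clade_c3c4", samples[6:12], cfg.n_clade)
    for k, sub in enumerate(subclones):
        members = samples[3 * k:3 * k + 3]
        add_edge(f"sub_{sub}", members, cfg.n_subclone_private)
        add_edge(f"pair_{sub}", members[1:], cfg.n_within_subclone)
        for s in members:
            add_edge(f"leaf_{s}", [s], cfg.n_sample_private)

    def sub_nwk(k: int) -> str:
        a, b, c = samples[3 * k:3 * k + 3]
        return f"({a},({b},{c}))"

    newick = (f"(diploid,(({sub_nwk(0)},{sub_nwk(1)}),"
              f"({sub_nwk(2)},{sub_nwk(3)})));")
    return CloneTree(samples=samples, subclone_of=subclone_of,
                     edge_mutations=edge_mutations, carriers=carriers,
                     newick=newick)


def spatial_layout(tree: CloneTree, rng: np.random.Generator,
                   patch_size: float = 10.0) -> pd.DataFrame:
    """Place subclones as contiguous spatial patches (2x2 quadrants)."""
    anchors = {
        "c1": (0.0, 0.0), "c2": (patch_size, 0.0),
        "c3": (0.0, patch_size), "c4": (patch_size, patch_size),
    }
    rows = []
    for s in tree.samples:
        sub = tree.subclone_of[s]
        ax, ay = anchors[sub]
        rows.append({
            "sample_id": s,
            "x": ax + rng.uniform(0, patch_size * 0.4),
            "y": ay + rng.uniform(0, patch_size * 0.4),
            "subclone": sub,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

DEFAULT_CNA_EVENTS = (
    # (carrier subclone or "truncal", chrom, start, end, copy)
    ("truncal", "chr2", 6_000_000, 8_000_000, 1),
    ("c2", "chr1", 2_000_000, 4_000_000, 3),
    ("c3", "chr2", 1_000_000, 3_000_000, 1),
    ("c4", "chr1", 6_000_000, 7_000_000, 4),
)


def copy_profile_for_sample(
    sample: str, tree: CloneTree, genome: GenomeModel,
    events=DEFAULT_CNA_EVENTS,
) -> np.ndarray:
    """Per-window integer copy number for one sample (diploid background)."""
    win = genome.windows
    copy = np.full(len(win), 2, dtype=int)
    sub = tree.subclone_of[sample]
    for carrier, chrom, start, end, cn in events:
        if carrier != "truncal" and carrier != sub:
            continue
        mask = (win["chrom"] == chrom) & (win["start"] < end) & (win["end"] > start)
        copy[mask.to_numpy()] = cn
    return copy


def default_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Unimodal amplification-efficiency curve peaking near GC 0.45."""
    return np.exp(-((np.asarray(gc) - 0.45) ** 2) / (2 * 0.12 ** 2))


def simulate_bin_counts(
    copy_per_bin: np.ndarray,
    bins: BinScheme,
    depth: int,
    gc_bias_curve=default_gc_bias,
    overdispersion_sigma: float = 0.3,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-bin read counts: Poisson around weight x copy x GC-bias x MDA noise.

    count_i ~ Poisson(depth * w_i * (copy_i / 2) * g(gc_i) * L_i) with
    L_i ~ lognormal(0, sigma) modelling amplification overdispersion; the
    intensity is normalized so counts total ~``depth``.
    """
    if overdispersion_sigma < 0:
        raise ValueError("overdispersion sigma must be non-negative")
    rng = np.random.default_rng(rng)
    table = bins.bins
    raw = (
        table["weight"].to_numpy()
        * (np.asarray(copy_per_bin, dtype=float) / 2.0)
        * gc_bias_curve(table["gc"].to_numpy())
    )
    if overdispersion_sigma > 0:
        raw = raw * rng.lognormal(0.0, overdispersion_sigma, size=len(raw))
    lam = depth * raw / raw.sum()
    return rng.poisson(lam)


def copy_per_bin(copy_per_window: np.ndarray, bins: BinScheme) -> np.ndarray:
    """Average per-window copy numbers into bins."""
    sums = bins.aggregate_window_values(copy_per_window.astype(float))
    counts = bins.aggregate_window_values(np.ones(len(copy_per_window)))
    return sums / counts


# ---------------------------------------------------------------------------
# pileups, dropout, errors
# ---------------------------------------------------------------------------

def simulate_site_pileup(
    ref: str, alt: str | None, rng: np.random.Generator,
    depth_mean: float = 30.0, vaf: float = 0.5,
    ado: float = 0.0, per_base_error: float = 1e-5,
    mda_sigma: float = 0.3,
) -> tuple[dict[str, int], bool]:
    """One sample's base counts at one site.

    Returns (counts, alt_dropped). With probability ``ado`` exactly one of
    the two alleles (chosen at random) is lost before amplification — this
    matches the way dropout is scored downstream (one allele missing at a
    covered site). Sequencing errors scatter reads onto random other bases.
    """
    depth = int(rng.poisson(depth_mean * rng.lognormal(0, mda_sigma)))
    counts = {b: 0 for b in "ACGT"}
    alt_dropped = False
    if depth == 0:
        return counts, alt_dropped
    p_alt = vaf if alt is not None else 0.0
    if alt is not None and ado > 0 and rng.random() < ado:
        if rng.random() < 0.5:
            p_alt, alt_dropped = 0.0, True
        else:
            p_alt = 1.0
    n_alt = rng.binomial(depth, p_alt) if alt is not None else 0
    counts[ref] = depth - n_alt
    if alt is not None:
        counts[alt] = n_alt
    n_err = rng.binomial(depth, per_base_error)
    for _ in range(n_err):
        victim = rng.choice([b for b in "ACGT" if counts[b] > 0])
        target = rng.choice([b for b in "ACGT" if b != victim])
        counts[victim] -= 1
        counts[target] += 1
    return counts, alt_dropped


def simulate_het_pileups(
    n_sites: int, cfg: SequencingConfig, genome_cfg: GenomeConfig,
    rng: np.random.Generator, sample_id: str = "cell1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confident heterozygous SNPs plus one cell's pileups (for ADO studies)."""
    used: set = set()
    sites = _draw_sites(n_sites, genome_cfg, rng, used)
    het_rows, pileup_rows = [], []
    for chrom, pos, a, b in sites:
        het_rows.append({"chrom": chrom, "pos": pos, "allele_a": a, "allele_b": b})
        counts, _ = simulate_site_pileup(
            ref=a, alt=b, rng=rng, depth_mean=cfg.site_depth_mean,
            ado=cfg.ado, per_base_error=cfg.per_base_error,
            mda_sigma=cfg.mda_sigma,
        )
        pileup_rows.append({
            "sample_id": sample_id, "chrom": chrom, "pos": pos, "ref": a,
            "nA": counts["A"], "nC": counts["C"], "nG": counts["G"], "nT": counts["T"],
        })
    return pd.DataFrame(het_rows), pd.DataFrame(pileup_rows)


def simulate_fpr_experiment(
    n_sites: int, fpr: float, rng: np.random.Generator,
    bulk_depth_mean: float = 40.0, min_bulk_cov: int = 20,
) -> tuple[pd.DataFrame, set]:
    """Bulk-confident homozygous sites and the single cell's somatic FP calls.

    Bulk counts are clean homozygous pileups; the cell's pipeline emits a
    spurious somatic call at each confident site with probability ``fpr``.
    """
    chroms = np.array(["chr1", "chr2"])[rng.integers(0, 2, n_sites)]
    pos = rng.choice(np.arange(1, 50_000_000), size=n_sites, replace=False)
    ref_idx = rng.integers(0, 4, n_sites)
    depth = rng.poisson(bulk_depth_mean, n_sites)
    counts = np.zeros((n_sites, 4), dtype=int)
    counts[np.arange(n_sites), ref_idx] = depth
    hom = pd.DataFrame({
        "chrom": chroms, "pos": pos,
        "nA": counts[:, 0], "nC": counts[:, 1],
        "nG": counts[:, 2], "nT": counts[:, 3],
    })
    confident = depth >= min_bulk_cov
    fp_mask = confident & (rng.random(n_sites) < fpr)
    calls = {(c, int(p)) for c, p in zip(chroms[fp_mask], pos[fp_mask])}
    return hom, calls


# ---------------------------------------------------------------------------
# pseudo-callers
# ---------------------------------------------------------------------------

def simulate_callers(
    sample_sites: dict[str, set],
    callers: tuple[CallerSpec, ...],
    genome_cfg: GenomeConfig,
    rng: np.random.Generator,
    dropped: dict[str, set] | None = None,
) -> pd.DataFrame:
    """Per-caller call tables from per-sample truth genotypes.

    Each true variant carried by a sample (and not lost to allelic
    dropout, per ``dropped``) is emitted by each caller independently with
    its sensitivity. False positives are injected per caller and sample as
    a Poisson number of uniform genome positions at the caller's per-base
    FPR.
    """
    dropped = dropped or {}
    genome_len = genome_cfg.n_chromosomes * genome_cfg.chrom_length
    rows = []
    for sample, sites in sample_sites.items():
        lost = dropped.get(sample, set())
        for caller in callers:
            for site in sorted(sites):  # stable order: set iteration is not
                if site in lost:
                    continue
                if rng.random() < caller.sensitivity:
                    chrom, pos, ref, alt = site
                    rows.append((sample, caller.name, chrom, pos, ref, alt))
            n_fp = rng.poisson(genome_len * caller.fpr)
            for _ in range(n_fp):
                chrom = f"chr{rng.integers(genome_cfg.n_chromosomes) + 1}"
                pos = int(rng.integers(1, genome_cfg.chrom_length + 1))
                ref, alt = rng.choice(4, size=2, replace=False)
                rows.append((sample, caller.name, chrom, pos,
                             str(BASES[ref]), str(BASES[alt])))
    return pd.DataFrame(
        rows, columns=["sample_id", "caller_id", "chrom", "pos", "ref", "alt"]
    )


# ---------------------------------------------------------------------------
# barcoded reads
# ---------------------------------------------------------------------------

def _mutate(seq: str, sub_rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < sub_rate:
            out[i] = str(rng.choice([b for b in "ACGT" if b != base]))
    return "".join(out)


def simulate_barcoded_reads(
    bset: BarcodeSet | dict[str, str],
    n_reads: int,
    rng: np.random.Generator | None = None,
    efficiencies: dict[str, float] | None = None,
    concentrations: dict[str, float] | None = None,
    sub_rate: float = 0.001,
    swap_rate: float = 0.0,
    species_map: dict[str, str] | None = None,
    read_len: int = 50,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Barcoded read pairs plus truth labels.

    Reads are distributed over barcodes proportionally to
    efficiency x concentration; read 2 starts with the (possibly
    substituted) barcode of record. With probability ``swap_rate`` a read's
    recorded barcode is replaced by a uniformly random different barcode
    while its truth labels (source barcode and species) are kept.
    """
    rng = np.random.default_rng(rng)
    codes = ({f"bc{i:03d}": s for i, s in enumerate(bset.barcodes, 1)}
             if isinstance(bset, BarcodeSet) else dict(bset))
    ids = list(codes)
    eff = np.array([(efficiencies or {}).get(b, 1.0) for b in ids])
    conc = np.array([(concentrations or {}).get(b, 1.0) for b in ids])
    p = eff * conc
    p = p / p.sum()
    assignment = rng.choice(len(ids), size=n_reads, p=p)
    blen = len(next(iter(codes.values())))
    reads, truth_rows = [], []
    for r, src_idx in enumerate(assignment):
        src = ids[src_idx]
        observed = src
        swapped = swap_rate > 0 and rng.random() < swap_rate
        if swapped:
            observed = ids[int(rng.choice([i for i in range(len(ids)) if i != src_idx]))]
        prefix = _mutate(codes[observed], sub_rate, rng)
        suffix = "".join(rng.choice(list("ACGT"), size=read_len - blen))
        seq1 = "".join(rng.choice(list("ACGT"), size=read_len))
        reads.append(ReadPair(
            read_id=f"read{r}", seq1=seq1, qual1="I" * read_len,
            seq2=prefix + suffix, qual2="I" * read_len,
        ))
        truth_rows.append({
            "read_id": f"read{r}", "true_barcode": src,
            "recorded_barcode": observed, "swapped": swapped,
            "species": (species_map or {}).get(src, "unknown"),
        })
    return reads, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# SV and kataegis truth
# ---------------------------------------------------------------------------

DEFAULT_SV_EVENTS = (
    ("DEL", "chr1", 1_200_000, 1_450_000),
    ("DUP", "chr1", 3_300_000, 3_900_000),
    ("INV", "chr1", 5_100_000, 5_600_000),
    ("DEL", "chr2", 2_200_000, 2_500_000),
    ("DUP", "chr2", 4_100_000, 4_700_000),
    ("INV", "chr2", 7_200_000, 7_800_000),
    ("TRA", "chr1", 8_000_000, 9_000_000),   # chrom2 = chr2, pos2 = last field
    ("DEL", "chr1", 6_200_000, 6_800_000),
    ("DUP", "chr2", 8_600_000, 9_200_000),
    ("DEL", "chr2", 5_300_000, 5_700_000),
)


def truth_sv_calls(events=DEFAULT_SV_EVENTS) -> list[SVCall]:
    """Materialize the default truth SV events as template calls."""
    calls = []
    for svtype, chrom, pos1, pos2 in events:
        chrom2 = "chr2" if svtype == "TRA" else chrom
        calls.append(SVCall(
            sample_id="truth", caller_id="truth", svtype=svtype,
            chrom1=chrom, pos1=pos1, chrom2=chrom2, pos2=pos2,
        ))
    return calls


def simulate_sv_calls(
    samples: list[str],
    rng: np.random.Generator,
    events=DEFAULT_SV_EVENTS,
    detect_prob: float = 0.9,
    jitter_bp: int = 200,
    n_private_artifacts: int = 4,
    genome_cfg: GenomeConfig | None = None,
) -> tuple[list[SVCall], list[SVCall]]:
    """Per-sample and bulk SV call tables around the truth events.

    Every truth event is detected in each sample by each caller with
    probability ``detect_prob`` and breakpoints jittered within
    ``jitter_bp``; manta calls are flagged somatic and gridss calls
    high-confidence. Each sample additionally carries private single-caller
    artifact calls that the tier filter must remove. Bulk detects every
    truth event.
    """
    genome_cfg = genome_cfg or GenomeConfig()
    truth = truth_sv_calls(events)
    flags = {"delly": "none", "manta": "somatic", "gridss": "high_confidence"}
    sample_calls, bulk_calls = [], []
    for t in truth:
        for s in samples:
            for caller, flag in flags.items():
                if rng.random() < detect_prob:
                    sample_calls.append(SVCall(
                        sample_id=s, caller_id=caller, svtype=t.svtype,
                        chrom1=t.chrom1,
                        pos1=t.pos1 + int(rng.integers(-jitter_bp, jitter_bp + 1)),
                        chrom2=t.chrom2,
                        pos2=t.pos2 + int(rng.integers(-jitter_bp, jitter_bp + 1)),
                        tier_flag=flag,
                    ))
        for caller, flag in flags.items():
            bulk_calls.append(SVCall(
                sample_id="bulk", caller_id=caller, svtype=t.svtype,
                chrom1=t.chrom1,
                pos1=t.pos1 + int(rng.integers(-jitter_bp, jitter_bp + 1)),
                chrom2=t.chrom2,
                pos2=t.pos2 + int(rng.integers(-jitter_bp, jitter_bp + 1)),
                tier_flag=flag,
            ))
    for s in samples:
        for _ in range(n_private_artifacts):
            svtype = str(rng.choice(["DEL", "DUP", "INV"]))
            chrom = f"chr{rng.integers(genome_cfg.n_chromosomes) + 1}"
            # keep artifacts away from truth breakpoints
            pos1 = int(rng.integers(100_000, genome_cfg.chrom_length // 2))
            caller = str(rng.choice(["delly", "manta", "gridss"]))
            sample_calls.append(SVCall(
                sample_id=s, caller_id=caller, svtype=svtype,
                chrom1=chrom, pos1=pos1, chrom2=chrom,
                pos2=pos1 + int(rng.integers(50_000, 200_000)),
                tier_flag="none",
            ))
    return sample_calls, bulk_calls


def kataegis_positions(
    chrom: str, start: int, n: int, spacing: int, rng: np.random.Generator
) -> np.ndarray:
    """Clustered 1-based positions with gaps uniform in [1, spacing]."""
    gaps = rng.integers(1, spacing + 1, size=n - 1)
    return start + np.concatenate([[0], np.cumsum(gaps)]).astype(np.int64)


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

@dataclass
class TruthBundle:
    clone_tree: CloneTree
    coordinates: pd.DataFrame
    copy_windows: dict[str, np.ndarray]
    sv_events: list[SVCall]
    kataegis: dict[str, np.ndarray]
    dropped: dict[str, set]


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: GenomeModel
    bins: BinScheme
    bin_counts: dict[str, np.ndarray]      # sample -> per-bin counts
    calls: pd.DataFrame                    # caller SNV table
    pileups: pd.DataFrame                  # per (sample, site) base counts
    sv_sample_calls: list[SVCall]
    sv_bulk_calls: list[SVCall]
    truth: TruthBundle


def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Generate a full synthetic experiment (deterministic given the seed)."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    genome = make_genome(config.genome, rng)
    tree = make_clone_tree(config.clones, config.genome, rng)
    coords = spatial_layout(tree, rng)

    from .cna import make_variable_bins
    bins = make_variable_bins(genome, config.n_bins)

    copy_windows, bin_counts = {}, {}
    for s in tree.samples:
        cw = copy_profile_for_sample(s, tree, genome)
        copy_windows[s] = cw
        cb = copy_per_bin(cw, bins)
        bin_counts[s] = simulate_bin_counts(
            cb, bins, config.sequencing.cna_depth,
            overdispersion_sigma=config.sequencing.mda_sigma, rng=rng,
        )

    # kataegis cluster on the truncal edge (carried by every sample)
    kat = {"chr1": kataegis_positions(
        "chr1", 4_500_000, config.kataegis_size, config.kataegis_spacing, rng)}
    kat_sites = [("chr1", int(p), "C", "T") for p in kat["chr1"]]
    tree.edge_mutations["truncal"] = tree.edge_mutations["truncal"] + kat_sites

    sample_sites = {s: tree.sample_sites(s) for s in tree.samples}
    all_sites = sorted(set().union(*sample_sites.values()))
    dropped: dict[str, set] = {}
    pileup_rows = []
    for s in tree.samples:
        lost = set()
        for site in all_sites:
            chrom, pos, ref, alt = site
            carried = site in sample_sites[s]
            counts, alt_dropped = simulate_site_pileup(
                ref, alt if carried else None, rng,
                depth_mean=config.sequencing.site_depth_mean,
                ado=config.sequencing.ado,
                per_base_error=config.sequencing.per_base_error,
                mda_sigma=config.sequencing.mda_sigma,
            )
            if carried and alt_dropped:
                lost.add(site)
            pileup_rows.append({
                "sample_id": s, "chrom": chrom, "pos": pos, "ref": ref,
                "nA": counts["A"], "nC": counts["C"],
                "nG": counts["G"], "nT": counts["T"],
            })
        dropped[s] = lost
    pileups = pd.DataFrame(pileup_rows)

    calls = simulate_callers(sample_sites, config.callers, config.genome,
                             rng, dropped=dropped)
    sv_sample, sv_bulk = simulate_sv_calls(
        tree.samples, rng, genome_cfg=config.genome)

    truth = TruthBundle(
        clone_tree=tree, coordinates=coords, copy_windows=copy_windows,
        sv_events=truth_sv_calls(), kataegis=kat, dropped=dropped,
    )
    return SimulatedDataset(
        config=config, genome=genome, bins=bins, bin_counts=bin_counts,
        calls=calls, pileups=pileups, sv_sample_calls=sv_sample,
        sv_bulk_calls=sv_bulk, truth=truth,
    )
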