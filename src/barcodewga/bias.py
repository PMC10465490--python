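"""Barcode-bias model and primer-mix rebalancing.

The read count of a barcode in a pooled barcoded-amplification library is
proportional to (primer concentration) x (barcode-specific amplification
efficiency). Because the efficiency is a stable property of the barcode
sequence, the bias can be inverted: after observing counts once, each
barcoded primer's concentration is scaled by mean(observed)/observed while
keeping both the barcoded-primer subtotal and the total hexamer
concentration fixed (the filler random hexamer absorbs nothing here since
the subtotal is preserved, but it is tracked to keep the mix invariant
explicit). Iterating this drives the coefficient of variation down to the
measurement-noise floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np


@dataclass
class PrimerMix:
    """Per-barcode primer concentrations plus filler hexamer (all in uM)."""

    concentrations: dict[str, float]
    filler_hexamer: float

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()) or self.filler_hexamer < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def barcoded_total(self) -> float:
        return sum(self.concentrations.values())

    @property
    def total_n6(self) -> float:
        """Total concentration of hexamer-bearing primers (barcoded + filler)."""
        return self.barcoded_total + self.filler_hexamer


@dataclass
class BiasProfile:
    """Barcode-specific amplification efficiency multipliers (mean ~1)."""

    efficiencies: dict[str, float]

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.efficiencies.values()):
            raise ValueError("efficiencies must be positive")

    @property
    def cv(self) -> float:
        return compute_cv(self.efficiencies)

    @classmethod
    def random(cls, barcode_ids, cv: float = 0.30, rng=None) -> "BiasProfile":
        """Lognormal efficiency draw with the requested coefficient of variation."""
        rng = np.random.default_rng(rng)
        sigma = math.sqrt(math.log(1 + cv**2))
        eff = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(list(barcode_ids)))
        return cls(dict(zip(barcode_ids, eff)))


def predict_counts(
    mix: PrimerMix, bias: BiasProfile, depth: float
) -> dict[str, float]:
    """Expected reads per barcode under the proportional model.

    expected_i is proportional to efficiency_i * concentration_i, normalized
    so the expectations sum to ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    weights = {
        bc: bias.efficiencies[bc] * conc for bc, conc in mix.concentrations.items()
    }
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("all effective concentrations are zero")
    return {bc: depth * w / total for bc, w in weights.items()}


def compute_cv(counts: Mapping[str, float] | np.ndarray) -> float:
    """Coefficient of variation: population standard deviation / mean."""
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=float
    )
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    return float(values.std(ddof=0) / mean)


def rebalance_mix(
    mix: PrimerMix,
    observed: Mapping[str, float],
    conc_floor_frac: float = 0.01,
) -> PrimerMix:
    """One concentration-balancing cycle.

    New concentration c_i' is proportional to c_i * mean(observed)/observed_i,
    rescaled so the barcoded-primer subtotal (and hence the total hexamer
    concentration) is exactly conserved. Concentrations are clipped below at
    ``conc_floor_frac`` of the mean concentration so a barcode can never be
    locked out of a later cycle.
    """
    if set(observed) != set(mix.concentrations):
        raise ValueError("observed counts must cover exactly the mix barcodes")
    if any(v <= 0 for v in observed.values()):
        bad = [k for k, v in observed.items() if v <= 0]
        raise ValueError(f"cannot invert zero/negative observed counts: {bad}")
    obs_mean = sum(observed.values()) / len(observed)
    raw = {
        bc: conc * obs_mean / observed[bc] for bc, conc in mix.concentrations.items()
    }
    floor = conc_floor_frac * sum(raw.values()) / len(raw)
    raw = {bc: max(c, floor) for bc, c in raw.items()}
    scale = mix.barcoded_total / sum(raw.values())
    return replace(mix, concentrations={bc: c * scale for bc, c in raw.items()})


def barcoded_fraction(mix: PrimerMix) -> float:
    """Percent of hexamer-bearing primers that carry a barcode."""
    if mix.total_n6 <= 0:
        raise ValueError("total N6 concentration must be positive")
    return 100.0 * mix.barcoded_total / mix.total_n6


#: average molar mass of one DNA base pair, g/mol
_BP_MOLAR_MASS = 650.0
_AVOGADRO = 6.02214076e23


def estimate_barcoded_depth(
    amplification_fold: float,
    barcoded_fraction: float,
    template_mass_pg: float = 6.6,
    product_len_bp: float = 10_000.0,
    captured_len_bp: float = 200.0,
    genome_len_bp: float = 3.0e9,
) -> float:
    """Expected genome-wide depth contributed by barcoded molecules.

    Converts amplified mass to molecule count at the amplicon length, takes
    the barcoded fraction of molecules, and assumes each contributes one
    captured fragment of ``captured_len_bp`` to the library:

        mass    = amplification_fold * template_mass_pg            (pg)
        n_mol   = mass(g) / (product_len_bp * 650 g/mol) * N_A
        depth   = n_mol * barcoded_fraction * captured_len_bp / genome_len_bp

    ``barcoded_fraction`` is a fraction in [0, 1], not a percent. The
    estimate is linear in every argument by construction; it is exposed as a
    parameterized calculator because the mapping from amplification fold to
    usable barcoded depth depends on capture details that vary per protocol.
    """
    args = dict(
        amplification_fold=amplification_fold,
        template_mass_pg=template_mass_pg,
        product_len_bp=product_len_bp,
        captured_len_bp=captured_len_bp,
        genome_len_bp=genome_len_bp,
    )
    for name, v in args.items():
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if not 0 <= barcoded_fraction <= 1:
        raise ValueError("barcoded_fraction must be in [0, 1]")
    mass_g = amplification_fold * template_mass_pg * 1e-12
    n_molecules = mass_g / (product_len_bp * _BP_MOLAR_MASS) * _AVOGADRO
    return n_molecules * barcoded_fraction * captured_len_bp / genome_len_bp


def balance_cycles(
    mix: PrimerMix,
    bias: BiasProfile,
    cycles: int = 3,
    depth: float = 1e6,
    noise_sigma: float = 0.0,
    rng=None,
) -> tuple[PrimerMix, list[float]]:
    """Simulate repeated observe-and-rebalance cycles.

    Each cycle predicts counts under the proportional model, optionally
    perturbs them with multiplicative lognormal measurement noise of the
    given sigma, and rebalances. Returns the final mix and the CV trajectory
    (initial CV first, one entry per cycle after).
    """
    rng = np.random.default_rng(rng)
    trajectory = []
    current = mix
    counts = predict_counts(current, bias, depth)
    trajectory.append(compute_cv(counts))
    for _ in range(cycles):
        observed = counts
        if noise_sigma > 0:
            noise = rng.lognormal(mean=0.0, sigma=noise_sigma, size=len(observed))
            observed = {
                bc: v * f for (bc, v), f in zip(observed.items(), noise)
            }
        current = rebalance_mix(current, observed)
        counts = predict_counts(current, bias, depth)
        trajectory.append(compute_cv(counts))
    return current, trajectory
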