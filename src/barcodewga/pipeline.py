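"""End-to-end analysis of a (synthetic) barcoded-amplification experiment.

Chains the library stages over one simulated dataset: copy-number
segmentation and Lorenz uniformity per microniche, consensus SNV
genotyping, the 1/NA/0 variant matrix, the rooted balanced-minimum-
evolution tree, mutation-profile PCA with Moran's I, tiered SV consensus
and kataegis detection. Useful as a smoke test and as the `run-all` CLI
backend.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cna import (SegmentationParams, call_states, cbs_segment, gc_normalize,
                  lorenz_auc, merge_levels)
from .phylo import (append_diploid_root, bme_tree, build_variant_matrix,
                    morans_i, profile_pca, variant_distances)
from .snv import CALLED, consensus_sites, genotype_samples
from .svkat import detect_kataegis, kataegis_filter_snvs, tiered_sv_filter
from .simulate import SimConfig, simulate_dataset


def run_pipeline(
    seed: int = 0,
    config: SimConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage on one synthetic dataset; return summary metrics."""
    config = config or SimConfig(seed=seed)
    ds = simulate_dataset(config)
    tree_truth = ds.truth.clone_tree
    summary: dict = {"seed": config.seed, "n_samples": len(tree_truth.samples)}

    # --- copy number and uniformity on the first microniche -----------------
    first = tree_truth.samples[0]
    ratios = gc_normalize(ds.bin_counts[first], ds.bins)
    segs = call_states(merge_levels(cbs_segment(ratios), ratios))
    summary["n_cna_segments"] = len(segs)
    _, auc = lorenz_auc(ds.bin_counts[first])
    summary["lorenz_auc"] = round(auc, 4)

    # --- consensus SNV genotyping -------------------------------------------
    sites = consensus_sites(ds.calls)
    callset = genotype_samples(sites, ds.calls, ds.pileups,
                               samples=tree_truth.samples)
    summary["n_confident_sites"] = len(sites)

    # --- phylogeny and spatial autocorrelation ------------------------------
    vm = build_variant_matrix(callset.genotypes, callset.coverage)
    tree = bme_tree(variant_distances(append_diploid_root(vm)))
    summary["newick"] = tree.newick()
    pcs = profile_pca(vm, n_components=2)
    coords = ds.truth.coordinates.set_index("sample_id")
    xy = coords.loc[vm.samples, ["x", "y"]].to_numpy()
    summary["moran_pc1"] = round(morans_i(pcs["PC1"].to_numpy(), coords=xy), 3)
    summary["moran_pc2"] = round(morans_i(pcs["PC2"].to_numpy(), coords=xy), 3)

    # --- SV and kataegis -----------------------------------------------------
    clusters = tiered_sv_filter(ds.sv_sample_calls, ds.sv_bulk_calls)
    summary["n_sv_clusters"] = len(clusters)
    detections = pd.DataFrame([
        {"sample_id": s, "chrom": c, "pos": p,
         "supporting_reads": 10}
        for s in tree_truth.samples
        for (c, p, _r, _a) in sorted(tree_truth.sample_sites(s))
    ])
    kept = kataegis_filter_snvs(detections)
    positions = {c: np.sort(g["pos"].unique()) for c, g in kept.groupby("chrom")}
    events = detect_kataegis(positions)
    summary["n_kataegis_events"] = len(events)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "tree.nwk", "w") as fh:
            fh.write(summary["newick"] + "\n")
        pd.Series({k: v for k, v in summary.items() if k != "newick"}).to_csv(
            out_dir / "summary.tsv", sep="\t", header=False)
    return summary
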