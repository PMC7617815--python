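"""Desk-scale parameter-recovery experiments.

Each experiment simulates data with known truth, runs the corresponding
analysis chain end to end, and reports the recovered quantity next to the
truth. These are the package's benchmark entry points, used by the test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import codonsub, genomescan, mapanchor, simcross, ygametolog

__all__ = [
    "recover_ds_xy",
    "recover_branch_omega",
    "recover_landscape",
    "recover_gene_density",
]


def recover_ds_xy(
    region: str,
    n_genes: int = 150,
    codons: int = 500,
    seed: int = 1,
    n_progeny_genomic: int = 10,
    coverage: float = 20.0,
) -> dict:
    """X:Y synonymous divergence through the full reconstruction chain.

    Simulates gametolog triplets for ``region`` and a genome-sequenced cross
    (two parents plus ``n_progeny_genomic`` F1 of alternating sex), then runs
    SNP classification, read partitioning, Y-consensus building and NG86
    estimation of each consensus against its X gametolog. Returns the
    across-gene mean dS (as a percentage) plus site-level precision/recall
    against the simulator's truth.
    """
    cfg = simcross.SimConfig(
        seed=seed,
        codons_per_gene=codons,
        cross=simcross.CrossConfig(
            n_f1_genomic=n_progeny_genomic,
            n_f2_transcriptomic=0,
            coverage_genomic=coverage,
        ),
    )
    rng = cfg.rng()
    genes = simcross.simulate_gametolog_triplets(cfg, region, rng, n_genes=n_genes)
    cross = simcross.simulate_cross(cfg, genes, rng)
    sites = ygametolog.classify_sites(cross.observations, cross.pedigree)
    assignments = ygametolog.partition_reads(cross.overlap, sites)
    ds_values = []
    consensus = {}
    for g in genes:
        cons = ygametolog.consensus_from_cross(cross, assignments, g.gene_id)
        consensus[g.gene_id] = cons
        est = codonsub.ng86_pairwise(g.x_cds, cons.sequence, gene_id=g.gene_id, label="XY")
        if est.dS is not None:
            ds_values.append(est.dS)
    truth_ds = [g.realized_ds_xy for g in genes]
    report = ygametolog.validate_against_truth(
        sites,
        cross.truth_sites,
        consensus=consensus,
        true_y={g.gene_id: g.y_cds for g in genes},
    )
    return {
        "region": region,
        "mean_ds_percent": 100.0 * float(np.mean(ds_values)),
        "truth_mean_ds_percent": 100.0 * float(np.mean(truth_ds)),
        "n": len(ds_values),
        **report,
    }


def recover_branch_omega(
    region: str = "qXdr",
    n_genes: int = 200,
    codons: int = 500,
    seed: int = 1,
) -> dict:
    """Per-branch dN/dS via pairwise NG86 and additive decomposition.

    Simulates triplets, estimates the three pairwise distances per gene,
    decomposes them onto the X, Y and outgroup branches, and reports both the
    pooled (summed dN over summed dS across genes; stable) and the mean of
    per-gene omega values (noisy ratios) for the X and Y branches.
    """
    cfg = simcross.SimConfig(seed=seed, codons_per_gene=codons)
    rng = cfg.rng()
    genes = simcross.simulate_gametolog_triplets(cfg, region, rng, n_genes=n_genes)
    triplets = [
        codonsub.GametologTriplet(
            gene_id=g.gene_id, region=g.region, x_cds=g.x_cds, y_cds=g.y_cds, og_cds=g.og_cds
        )
        for g in genes
    ]
    est = codonsub.estimates_table(triplets)
    summary = codonsub.aggregate_region(est).set_index("region").loc[region]
    targets = cfg.branch_targets[region]
    return {
        "region": region,
        "omega_y_pooled": float(summary["omega_Y_pooled"]),
        "omega_x_pooled": float(summary["omega_X_pooled"]),
        "omega_y_mean": summary["omega_Y_mean"],
        "omega_x_mean": summary["omega_X_mean"],
        "ds_xy_mean": summary["dS_XY_mean"],
        "truth_omega_y": targets.omega_y,
        "truth_omega_x": targets.omega_x,
        "n": int(summary["n_genes"]),
        "estimates": est,
    }


def recover_landscape(
    seed: int = 1,
    n_markers: int = 400,
    cm_noise_sd: float = 0.0,
    window: float = 10e6,
    step: float = 2e6,
    threshold: float = 0.25,
    geometry: simcross.MapGeometry | None = None,
) -> dict:
    """Recombination-landscape segmentation on a synthetic X-like chromosome.

    Simulates a genetic map over the default X-like geometry (two distal
    recombining segments, suppressed centre), anchors the markers from the
    hit table, fits the Marey map, estimates windowed rates and segments the
    chromosome. Reports the pericentromeric length and the mean rate over
    windows fully contained in distal regions, next to the simulated truth.
    """
    geom = geometry or simcross.MapGeometry(n_markers=n_markers, cm_noise_sd=cm_noise_sd)
    cfg = simcross.SimConfig(seed=seed, map_geometry=geom)
    sim = simcross.simulate_genetic_map(cfg, cfg.rng())
    anchors = mapanchor.anchor_markers(sim.hits)
    marey = mapanchor.build_marey_map(anchors, sim.markers, sex="female", chrom=geom.chrom)
    profile = mapanchor.recombination_rate(marey, geom.chrom_length, window=window, step=step)
    seg = mapanchor.segment_regions(profile, geom.chrom_length, threshold=threshold)
    if seg.boundaries is None:
        peri_mb = 0.0
    else:
        peri_mb = (seg.boundaries[1] - seg.boundaries[0]) / 1e6
    distal = mapanchor.windows_in_region(profile, seg, ("distal_p", "distal_q"))
    true_b = geom.boundaries
    return {
        "peri_length_mb": peri_mb,
        "distal_rate_mean": float(distal["rate"].dropna().mean()),
        "n_distal_windows": int(distal["rate"].notna().sum()),
        "boundaries": seg.boundaries,
        "truth_boundaries": true_b,
        "truth_peri_length_mb": (true_b[1] - true_b[0]) / 1e6,
        "truth_distal_rate": geom.rate_distal,
        "segmentation": seg,
        "profile": profile,
        "map_sim": sim,
    }


def recover_gene_density(
    segmentation: mapanchor.RegionSegmentation | None = None,
    seed: int = 1,
    distal_density: float = 17.8,
    peri_density: float = 6.6,
    window: float = 1e6,
    step: float = 0.2e6,
) -> dict:
    """Windowed gene-density recovery on the segmented X-like chromosome.

    Places genes uniformly at the given per-region densities (genes/Mb) in
    the distal and pericentromeric intervals, runs the sliding windower in
    count mode, and averages windows fully contained in each region class.
    """
    if segmentation is None:
        segmentation = recover_landscape(seed=seed)["segmentation"]
    rng = np.random.default_rng(seed)
    densities = {"distal_p": distal_density, "distal_q": distal_density,
                 "pericentromeric": peri_density}
    genes = simcross.simulate_gene_positions(segmentation.intervals, densities, rng)
    track = genomescan.density_windows(
        genes[["start", "end"]], segmentation.chrom_length, window=window, step=step,
        mode="count_per_mb",
    )

    def region_mean(labels):
        keep = np.zeros(len(track), dtype=bool)
        for start, end, label in segmentation.intervals:
            if label in labels:
                keep |= (track["start"].to_numpy() >= start) & (track["end"].to_numpy() <= end)
        return float(track.loc[keep, "value"].mean())

    return {
        "distal_mean": region_mean(("distal_p", "distal_q")),
        "peri_mean": region_mean(("pericentromeric",)),
        "n_genes": len(genes),
        "n_windows": len(track),
        "truth_distal_density": distal_density,
        "truth_peri_density": peri_density,
        "track": track,
    }
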