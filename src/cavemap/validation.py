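"""Self-validation experiments on synthetic data with known ground truth.

These drivers run the full analysis on generated datasets and measure how
well the true structure is recovered: linkage-group membership and marker
order, map length, genome-scan power for a fully penetrant recessive trait
against permutation thresholds, and the false-discard rate of the
segregation-distortion filter under the null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cavemap import qtl
from cavemap.linkage import (
    GeneticMap,
    LinkageGroup,
    build_map,
    em_rf,
)
from cavemap.marker_qc import (
    codes_matrix,
    retained,
    screen_and_code,
)
from cavemap.simcross import SimConfig, simulate_cross


def genetic_map_from_truth(truemap) -> GeneticMap:
    """The ground-truth map as a GeneticMap object."""
    groups = []
    for chrom, ids in truemap.chromosomes.items():
        pos = truemap.markers.loc[ids, "pos_cM"].to_numpy(dtype=float)
        groups.append(LinkageGroup(f"chr{chrom}", list(ids), pos - pos[0]))
    return GeneticMap(groups)


def true_codes_frame(truemap, panelset) -> pd.DataFrame:
    """Integer genotype codes derived from the true allele assignment."""
    rows = []
    for mid in panelset.marker_ids:
        calls = panelset.f2.loc[mid]
        lut = {truemap.markers.at[mid, "surface_allele"]: 0,
               truemap.markers.at[mid, "het_code"]: 1,
               truemap.markers.at[mid, "cave_allele"]: 2}
        rows.append(calls.map(lambda c: lut.get(c, -1)).to_numpy())
    return pd.DataFrame(np.array(rows, dtype=np.int8),
                        index=panelset.marker_ids,
                        columns=panelset.f2.columns)


def recovery_experiment(seed: int, config: SimConfig | None = None) -> dict:
    """QC + de-novo map construction on the default 25-chromosome cross.

    Returns group-membership labels (true chromosome vs assigned group) for
    every placed marker, the per-group Kendall tau between true and fitted
    marker positions, and the total-length recovery ratio.
    """
    from scipy.stats import kendalltau

    if config is None:
        config = SimConfig(seed=seed)
    else:
        config = SimConfig(**{**config.__dict__, "seed": seed})
    truemap, panelset, _ = simulate_cross(config)
    coded, _ = screen_and_code(panelset)
    ids, codes = codes_matrix(retained(coded))
    gmap, audit = build_map(ids, codes)
    labels_true, labels_pred, taus = [], [], []
    for group in gmap.groups:
        for mid in group.markers:
            labels_true.append(int(truemap.chromosome_of(mid)))
            labels_pred.append(group.group_id)
        if group.n_markers >= 2:
            true_pos = truemap.markers.loc[group.markers, "pos_cM"]
            tau, _ = kendalltau(true_pos, group.positions)
            taus.append(abs(float(tau)))
    true_length = sum(
        truemap.markers[truemap.markers.chromosome == c].pos_cM.max()
        for c in truemap.chromosomes)
    return {
        "labels_true": labels_true,
        "labels_pred": labels_pred,
        "n_groups": len(gmap.groups),
        "taus": taus,
        "min_abs_tau": min(taus) if taus else float("nan"),
        "map_length_cM": gmap.total_length_cM,
        "true_length_cM": float(true_length),
        "length_ratio": gmap.total_length_cM / true_length,
    }


QTL_SIM = dict(n_chromosomes=3, markers_per_chromosome=15,
               chrom_length_cM=60.0, n_f2=170, trait_locus=(1, 30.0))
TRAIT_MARKER = "M01_008"    # the typed marker at 30 cM on chromosome 1


def qtl_power_replicate(seed: int, n_perm: int = 1000, alpha: float = 0.001,
                        methods=("mr", "em", "hk")) -> dict:
    """One replicate of the recessive-trait scan-and-threshold experiment.

    Simulates a fresh cross with a fully penetrant recessive trait at a
    typed marker, scans with MR/EM/HK on the true map (markers-only grid),
    and compares each method's genome-wide peak against its alpha-level
    permutation threshold.
    """
    config = SimConfig(**QTL_SIM, seed=seed)
    truemap, panelset, phen = simulate_cross(config)
    gmap = genetic_map_from_truth(truemap)
    codes = true_codes_frame(truemap, panelset)
    grid = qtl.genotype_probs(gmap, codes, step_cM=0)
    y = phen.to_numpy()
    out = {}
    for method in methods:
        pos, lod = (s := qtl.scanone(y, grid, methods=(method,))).peak(method)
        threshold = qtl.permutation_threshold(
            y, grid, method, n_perm=n_perm, alphas=(alpha,),
            seed=seed + 1)[alpha]
        out[method] = {
            "peak_marker": pos["marker"],
            "peak_lod": lod,
            "threshold": threshold,
            "hit": (pos["marker"] == TRAIT_MARKER) and lod > threshold,
        }
    return out


def qtl_power_experiment(n_replicates: int, seed: int,
                         n_perm: int = 1000, alpha: float = 0.001) -> dict:
    hits = 0
    for k in range(n_replicates):
        rep = qtl_power_replicate(seed + 1000 * k, n_perm=n_perm, alpha=alpha)
        hits += all(r["hit"] for r in rep.values())
    return {"n_replicates": n_replicates, "n_hits": hits,
            "power_pct": 100.0 * hits / n_replicates}


def mr_hk_identity_check(seed: int) -> float:
    """Max |MR - HK| over typed markers on a complete-data cross (should be
    numerically zero: with indicator genotype probabilities both methods fit
    the same genotype-class regression)."""
    config = SimConfig(n_chromosomes=2, markers_per_chromosome=12,
                       chrom_length_cM=50.0, n_f2=170, missing_rate=0.0,
                       error_rate=0.0, trait_locus=(1, 25.0), seed=seed)
    truemap, panelset, phen = simulate_cross(config)
    gmap = genetic_map_from_truth(truemap)
    codes = true_codes_frame(truemap, panelset)
    grid = qtl.genotype_probs(gmap, codes, step_cM=0, epsilon=0.0)
    res = qtl.scanone(phen.to_numpy(), grid, methods=("mr", "hk"))
    typed = sorted(grid.marker_codes)
    return float(np.nanmax(np.abs(res.lod["mr"][typed] - res.lod["hk"][typed])))


def null_filter_experiment(n_markers: int, seed: int,
                           chi2_cutoff: float = 50.0) -> dict:
    """False-discard rate of the chi2 > cutoff filter under clean 1:2:1
    segregation at n = 170, measured through the full QC path."""
    per_sim = 1000
    n_sims = int(np.ceil(n_markers / per_sim))
    distorted = total = 0
    for k in range(n_sims):
        config = SimConfig(seed=seed + k)      # default 25 x 40 = 1000 markers
        _, panelset, _ = simulate_cross(config)
        coded, report = screen_and_code(panelset, chi2_cutoff=chi2_cutoff)
        distorted += report.distorted
        total += report.screened
    return {"n_markers_screened": total, "n_discarded": distorted,
            "discard_pct": 100.0 * distorted / total}


def em_random_tables(n_tables: int, seed: int, max_count: int = 30):
    """Random 9-cell tables and their EM recombination-fraction estimates."""
    rng = np.random.default_rng(seed)
    tables = rng.integers(0, max_count, size=(n_tables, 3, 3)).astype(float)
    tables = tables[tables.sum(axis=(1, 2)) >= 2]
    return tables, em_rf(tables)
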