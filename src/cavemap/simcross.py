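"""Synthetic GBS-style F2 intercross datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: founder panels fixed for alternate alleles (with configurable
planted artifacts), heterozygous F1 individuals, F2 genotypes produced by
independent meioses through a Markov recombination model whose per-interval
recombination probability is the Kosambi inverse of the true cM gap, per-call
genotyping error and missingness, markers embedded on genome scaffolds with a
planted orientation, paralog decoy alignments, and a fully penetrant
recessive Mendelian trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cavemap.iupac import MISSING, NUCLEOTIDES, het_code
from cavemap.linkage import kosambi_inverse

@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cross.

    Defaults mirror the emulated study design: 25 chromosomes (the karyotype
    number), four individuals per founder/F1 panel, 170 F2 individuals, and a
    ~84 cM chromosome (a ~2100 cM genome over 25 groups).  Error and
    missingness rates are free parameters of the generator (the real data's
    rates are unpublished); 0.5% call error and 2% missingness are typical of
    filtered GBS genotype matrices.
    """

    n_chromosomes: int = 25
    markers_per_chromosome: int = 40
    chrom_length_cM: float = 84.0
    n_f2: int = 170
    panel_size: int = 4
    missing_rate: float = 0.02
    error_rate: float = 0.005
    frac_monomorphic: float = 0.0
    frac_parentNA: float = 0.0
    frac_distorted: float = 0.0
    distortion_strength: float = 0.5
    trait_locus: tuple[int, float] | None = None
    seed: int = 0
    bp_per_cM: float = 550_000.0
    scaffold_length_bp: int = 5_000_000

    def __post_init__(self):
        for name in ("missing_rate", "error_rate", "frac_monomorphic",
                     "frac_parentNA", "frac_distorted", "distortion_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chromosomes", "markers_per_chromosome", "n_f2",
                     "panel_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.chrom_length_cM <= 0:
            raise ValueError("chrom_length_cM must be positive")
        if self.frac_monomorphic + self.frac_parentNA + self.frac_distorted > 1:
            raise ValueError("artifact fractions must sum to <= 1")


@dataclass
class TrueMap:
    """Simulation ground truth.

    ``markers``: one row per marker (index = marker id) with true chromosome,
    cM position, allele assignment, scaffold placement and artifact label.
    ``scaffolds``: per-scaffold chromosome, extent and planted orientation.
    """

    markers: pd.DataFrame
    scaffolds: pd.DataFrame
    chromosomes: dict[int, list[str]] = field(default_factory=dict)

    def chromosome_of(self, marker: str) -> int:
        return int(self.markers.at[marker, "chromosome"])


@dataclass
class MarkerPanelSet:
    """Raw IUPAC genotype calls for all panels plus the 64-bp tag pair."""

    marker_ids: list[str]
    tags: pd.DataFrame           # columns: tag_surface, tag_cave
    surface: pd.DataFrame        # markers x surface panel individuals
    cave: pd.DataFrame
    f1: pd.DataFrame
    f2: pd.DataFrame             # markers x F2 individuals

    def copy(self) -> "MarkerPanelSet":
        return MarkerPanelSet(
            list(self.marker_ids), self.tags.copy(), self.surface.copy(),
            self.cave.copy(), self.f1.copy(), self.f2.copy(),
        )


def _random_tag(rng, surface_allele: str, cave_allele: str) -> tuple[str, str]:
    """A 64-bp tag pair differing only at the embedded SNP (position 32)."""
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=64)
    s = seq.copy()
    s[31] = surface_allele
    c = seq.copy()
    c[31] = cave_allele
    return "".join(s), "".join(c)


def _class_calls(classes: np.ndarray, surface: str, cave: str) -> np.ndarray:
    """Map genotype classes {0,1,2} to IUPAC calls for one marker."""
    table = np.array([surface, het_code(surface, cave), cave])
    return table[classes]


def _apply_error_missing(classes: np.ndarray, rng, error_rate, missing_rate):
    """Symmetric call-swap error then independent missingness.

    An erroneous call swaps to one of the two other genotype classes
    uniformly; missing entries are marked -1.
    """
    out = classes.copy()
    if error_rate > 0:
        err = rng.random(out.shape) < error_rate
        shift = rng.integers(1, 3, size=out.shape)
        out = np.where(err, (out + shift) % 3, out)
    if missing_rate > 0:
        out = np.where(rng.random(out.shape) < missing_rate, -1, out)
    return out


def _calls_frame(class_matrix, surface_alleles, cave_alleles, marker_ids, columns):
    """Build a call DataFrame from a marker-by-individual class matrix."""
    rows = []
    for k, mid in enumerate(marker_ids):
        calls = np.where(
            class_matrix[k] < 0,
            MISSING,
            _class_calls(np.clip(class_matrix[k], 0, 2), surface_alleles[k],
                         cave_alleles[k]),
        )
        rows.append(calls)
    return pd.DataFrame(rows, index=marker_ids, columns=columns)


def simulate_cross(config: SimConfig):
    """Simulate the full cross.

    Returns
    -------
    truemap : TrueMap
    panelset : MarkerPanelSet
    phenotypes : pandas.Series of 0/1 per F2 individual (all zero when no
        trait locus is configured).
    """
    rng = np.random.default_rng(config.seed)
    mpc = config.markers_per_chromosome
    length = config.chrom_length_cM

    if config.trait_locus is not None:
        tchrom, tpos = config.trait_locus
        if not (1 <= tchrom <= config.n_chromosomes) or not (0 <= tpos <= length):
            raise ValueError(f"trait locus {config.trait_locus} outside the simulated map")

    marker_ids: list[str] = []
    rows = []
    chromosomes: dict[int, list[str]] = {}
    f2_classes_cols = []
    trait_geno = None

    nucleotides = sorted(NUCLEOTIDES)
    f2_ids = [f"F2_{i + 1:03d}" for i in range(config.n_f2)]

    for chrom in range(1, config.n_chromosomes + 1):
        if mpc == 1:
            positions = np.array([length / 2.0])
        else:
            positions = np.linspace(0.0, length, mpc)
        ids = [f"M{chrom:02d}_{i + 1:03d}" for i in range(mpc)]
        chromosomes[chrom] = ids
        marker_ids.extend(ids)

        # latent trait locus joins the meiosis chain on its chromosome
        sim_pos = positions
        trait_idx = None
        if config.trait_locus is not None and chrom == config.trait_locus[0]:
            sim_pos = np.sort(np.append(positions, config.trait_locus[1]))
            trait_idx = int(np.searchsorted(sim_pos, config.trait_locus[1]))
            # searchsorted may land left of an equal marker position; locate exactly
            trait_idx = int(np.where(sim_pos == config.trait_locus[1])[0][0])

        r = kosambi_inverse(np.diff(sim_pos))
        n_gam = 2 * config.n_f2
        first = (rng.random(n_gam) < 0.5).astype(np.int8)
        if len(sim_pos) > 1:
            switches = (rng.random((n_gam, len(sim_pos) - 1)) < r).astype(np.int8)
            paths = (first[:, None] + np.concatenate(
                [np.zeros((n_gam, 1), dtype=np.int8),
                 np.cumsum(switches, axis=1)], axis=1)) % 2
        else:
            paths = first[:, None]
        genotypes = paths[0::2] + paths[1::2]      # (n_f2, n_positions), cave dose

        if trait_idx is not None:
            trait_geno = genotypes[:, trait_idx].copy()
            keep = np.ones(len(sim_pos), dtype=bool)
            if len(sim_pos) == mpc + 1:
                keep[trait_idx] = False
            genotypes = genotypes[:, keep]

        f2_classes_cols.append(genotypes.T)        # (mpc, n_f2)

        for i, mid in enumerate(ids):
            s_allele = nucleotides[rng.integers(0, 4)]
            c_allele = nucleotides[(nucleotides.index(s_allele) + rng.integers(1, 4)) % 4]
            rows.append({"marker": mid, "chromosome": chrom,
                         "pos_cM": positions[i],
                         "surface_allele": s_allele, "cave_allele": c_allele})

    truth = pd.DataFrame(rows).set_index("marker")
    truth["het_code"] = [het_code(s, c) for s, c in
                         zip(truth.surface_allele, truth.cave_allele)]
    truth["artifact"] = "none"

    # scaffold placement with planted per-scaffold orientation
    scaffolds = _place_on_scaffolds(truth, config, rng)

    f2_classes = np.vstack(f2_classes_cols)        # (m, n_f2), clean classes

    phenotypes = pd.Series(0, index=f2_ids, name="phenotype", dtype=int)
    if trait_geno is not None:
        phenotypes[:] = (trait_geno == 2).astype(int)

    panel = config.panel_size
    m = len(marker_ids)
    surface_classes = np.zeros((m, panel), dtype=np.int8)
    cave_classes = np.full((m, panel), 2, dtype=np.int8)
    f1_classes = np.ones((m, panel), dtype=np.int8)

    surface_classes = _apply_error_missing(surface_classes, rng,
                                           config.error_rate, config.missing_rate)
    cave_classes = _apply_error_missing(cave_classes, rng,
                                        config.error_rate, config.missing_rate)
    f1_classes = _apply_error_missing(f1_classes, rng,
                                      config.error_rate, config.missing_rate)
    f2_obs = _apply_error_missing(f2_classes, rng,
                                  config.error_rate, config.missing_rate)

    s_alleles = truth.surface_allele.to_numpy()
    c_alleles = truth.cave_allele.to_numpy()
    tags = pd.DataFrame(
        [_random_tag(rng, s, c) for s, c in zip(s_alleles, c_alleles)],
        index=marker_ids, columns=["tag_surface", "tag_cave"],
    )

    panelset = MarkerPanelSet(
        marker_ids=marker_ids,
        tags=tags,
        surface=_calls_frame(surface_classes, s_alleles, c_alleles, marker_ids,
                             [f"S{i + 1}" for i in range(panel)]),
        cave=_calls_frame(cave_classes, s_alleles, c_alleles, marker_ids,
                          [f"C{i + 1}" for i in range(panel)]),
        f1=_calls_frame(f1_classes, s_alleles, c_alleles, marker_ids,
                        [f"F1_{i + 1}" for i in range(panel)]),
        f2=_calls_frame(f2_obs, s_alleles, c_alleles, marker_ids, f2_ids),
    )
    truemap = TrueMap(markers=truth, scaffolds=scaffolds, chromosomes=chromosomes)

    if config.frac_monomorphic or config.frac_parentNA or config.frac_distorted:
        panelset = plant_artifacts(panelset, config, rng=rng, truemap=truemap)
    return truemap, panelset, phenotypes


def _place_on_scaffolds(truth: pd.DataFrame, config: SimConfig, rng):
    """Tile chromosomes with scaffolds; randomly orient each scaffold."""
    chrom_bp = int(round(config.chrom_length_cM * config.bp_per_cM))
    bp = (truth.pos_cM.to_numpy() * config.bp_per_cM).round().astype(np.int64) + 1
    bp = np.minimum(bp, chrom_bp)
    scaf_idx = (bp - 1) // config.scaffold_length_bp
    scaffold_ids = [f"scf{c:02d}_{k:02d}" for c, k in
                    zip(truth.chromosome, scaf_idx)]
    truth["chrom_bp"] = bp
    truth["scaffold"] = scaffold_ids

    rows = []
    offsets = np.empty(len(truth), dtype=np.int64)
    for scaffold, sub in truth.groupby("scaffold", sort=True):
        chrom = int(sub.chromosome.iloc[0])
        k = int((sub.chrom_bp.iloc[0] - 1) // config.scaffold_length_bp)
        start = k * config.scaffold_length_bp
        slen = min(config.scaffold_length_bp, chrom_bp - start)
        orientation = "forward" if rng.random() < 0.5 else "reverse"
        local = sub.chrom_bp.to_numpy() - start
        if orientation == "reverse":
            local = slen - local + 1
        offsets[truth.index.get_indexer(sub.index)] = local
        rows.append({"scaffold": scaffold, "chromosome": chrom,
                     "start_bp": start + 1, "length_bp": slen,
                     "orientation": orientation})
    truth["scaffold_bp"] = offsets
    return pd.DataFrame(rows).set_index("scaffold")


def plant_artifacts(panelset: MarkerPanelSet, config: SimConfig, rng=None,
                    truemap: TrueMap | None = None) -> MarkerPanelSet:
    """Plant QC-failure artifacts at the configured marker fractions.

    Disjoint marker subsets are made (a) parent-unassignable (both founder
    panels scrambled into 2-2 splits), (b) monomorphic (every F2 call is the
    surface homozygote), (c) segregation-distorted (F2 genotype classes
    resampled with the ``CC`` class down-weighted by ``1 - s``).  Planted
    marker ids are recorded in the ground truth when ``truemap`` is given.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    out = panelset.copy()
    m = len(out.marker_ids)
    n_na = int(round(config.frac_parentNA * m))
    n_mono = int(round(config.frac_monomorphic * m))
    n_dist = int(round(config.frac_distorted * m))
    chosen = rng.choice(m, size=min(m, n_na + n_mono + n_dist), replace=False)
    na_idx = chosen[:n_na]
    mono_idx = chosen[n_na:n_na + n_mono]
    dist_idx = chosen[n_na + n_mono:]

    marker_ids = np.asarray(out.marker_ids)
    panel = config.panel_size
    half = panel // 2

    for k in na_idx:
        mid = marker_ids[k]
        s = out.tags.at[mid, "tag_surface"][31]
        c = out.tags.at[mid, "tag_cave"][31]
        scramble = [s] * half + [c] * (panel - half)
        out.surface.loc[mid] = scramble
        out.cave.loc[mid] = scramble[::-1]

    for k in mono_idx:
        mid = marker_ids[k]
        out.f2.loc[mid] = out.tags.at[mid, "tag_surface"][31]

    if len(dist_idx):
        s = config.distortion_strength
        probs = np.array([1.0, 2.0, 1.0 - s])
        probs = probs / probs.sum()
        n_f2 = out.f2.shape[1]
        for k in dist_idx:
            mid = marker_ids[k]
            classes = rng.choice(3, size=n_f2, p=probs).astype(np.int8)
            classes = _apply_error_missing(classes[None, :], rng,
                                           config.error_rate,
                                           config.missing_rate)[0]
            sa = out.tags.at[mid, "tag_surface"][31]
            ca = out.tags.at[mid, "tag_cave"][31]
            out.f2.loc[mid] = np.where(
                classes < 0, MISSING,
                _class_calls(np.clip(classes, 0, 2), sa, ca))

    if truemap is not None:
        truemap.markers.loc[marker_ids[na_idx], "artifact"] = "parent_na"
        truemap.markers.loc[marker_ids[mono_idx], "artifact"] = "monomorphic"
        truemap.markers.loc[marker_ids[dist_idx], "artifact"] = "distorted"
    return out


# ---------------------------------------------------------------------------
# Simulated alignment-hit tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]

#: per-route fraction of conserved markers actually recovered by that route,
#: emulating the observed information content of the three search strategies
DEFAULT_ROUTE_COVERAGE = {"direct": 0.05, "genomic": 0.75, "transcriptomic": 0.40}


def simulate_hit_tables(truemap: TrueMap, decoy_rate: float,
                        conserved_fraction: float, seed: int,
                        route_coverage: dict[str, float] | None = None,
                        strong_decoy_rate: float = 0.2,
                        target_bp_per_cM: float = 600_000.0):
    """Simulate 12-column tabular alignments against a fictitious target genome.

    Chromosome ``k`` of the simulated map corresponds to target chromosome
    ``Dchr<k>``.  A ``conserved_fraction`` of markers receive a true-target
    hit (lowest e-value); with probability ``decoy_rate`` a conserved marker
    additionally picks up 1-2 paralog decoy hits on other chromosomes with
    higher e-values; at most three distinct targets per query.  A
    ``strong_decoy_rate`` fraction of decoys emulate recent paralogs whose
    alignment outranks the true hit, the failure mode that the
    positional-support resolution exists to correct.

    Returns ``(tables, truth)`` where ``tables`` maps route name to a
    DataFrame in the 12-column tabular format and ``truth`` maps marker id to
    its true target chromosome.
    """
    if not 0 <= decoy_rate <= 1 or not 0 <= conserved_fraction <= 1:
        raise ValueError("rates must be in [0, 1]")
    coverage = dict(DEFAULT_ROUTE_COVERAGE)
    if route_coverage:
        coverage.update(route_coverage)
    rng = np.random.default_rng(seed)
    markers = truemap.markers
    n_target = int(markers.chromosome.max())
    conserved = pd.Series(rng.random(len(markers)) < conserved_fraction,
                          index=markers.index)
    truth = pd.Series(
        [f"Dchr{c}" for c in markers.chromosome], index=markers.index,
        name="true_target",
    )[conserved]

    tables = {}
    for route in ("direct", "genomic", "transcriptomic"):
        qlen = {"direct": 64, "genomic": 2000, "transcriptomic": 1200}[route]
        rows = []
        for mid in markers.index[conserved]:
            if rng.random() >= coverage[route]:
                continue
            chrom = int(markers.at[mid, "chromosome"])
            pos = float(markers.at[mid, "pos_cM"])
            rows.append(_hit_row(rng, mid, f"Dchr{chrom}",
                                 int(pos * target_bp_per_cM) + 1,
                                 qlen, true_hit=True))
            if route == "direct" and rng.random() < 0.5:
                # second allele's alignment on the same target, slightly worse
                rows.append(_hit_row(rng, mid, f"Dchr{chrom}",
                                     int(pos * target_bp_per_cM) + 1,
                                     qlen, true_hit=True, degrade=True))
            if rng.random() < decoy_rate:
                others = [c for c in range(1, n_target + 1) if c != chrom]
                n_decoy = min(int(rng.integers(1, 3)), len(others))
                decoy_chroms = rng.choice(others, size=n_decoy, replace=False)
                for dc in decoy_chroms:
                    dpos = int(rng.uniform(0, 84) * target_bp_per_cM) + 1
                    rows.append(_hit_row(rng, mid, f"Dchr{dc}", dpos, qlen,
                                         true_hit=False,
                                         strong=rng.random() < strong_decoy_rate))
        tables[route] = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return tables, truth


def _hit_row(rng, qseqid, sseqid, sstart, qlen, true_hit, degrade=False,
             strong=False):
    length = int(min(qlen, rng.integers(55, 65) if qlen == 64
                     else rng.integers(int(qlen * 0.6), qlen + 1)))
    if true_hit:
        evalue = 10.0 ** (-rng.uniform(20, 40))
        pident = float(rng.uniform(92, 100))
    elif strong:
        # recent paralog: outranks the orthologous alignment
        evalue = 10.0 ** (-rng.uniform(40, 50))
        pident = float(rng.uniform(95, 100))
    else:
        evalue = 10.0 ** (-rng.uniform(1, 10))
        pident = float(rng.uniform(80, 92))
    if degrade:
        evalue *= 10.0 ** rng.uniform(1, 3)
        pident = max(80.0, pident - rng.uniform(0.5, 2.0))
    mismatch = int(round(length * (100 - pident) / 100))
    send = sstart + length - 1
    if rng.random() < 0.3:
        sstart, send = send, sstart
    return {
        "qseqid": qseqid, "sseqid": sseqid, "pident": round(pident, 2),
        "length": length, "mismatch": mismatch, "gapopen": 0,
        "qstart": 1, "qend": length, "sstart": sstart, "send": send,
        "evalue": evalue, "bitscore": round(2.0 * length - 3 * mismatch, 1),
    }


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a replaced seed."""
    return replace(config, seed=seed)
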