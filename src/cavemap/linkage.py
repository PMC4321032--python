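"""Genetic-map construction for an F2 intercross with codominant SNP markers.

Pipeline: two-point recombination fractions by EM over the 9-cell joint
genotype table, independence-LOD single-linkage grouping with a threshold
ladder, incremental-insertion marker ordering against a weighted least-squares
criterion (a regression-mapping style algorithm), Kosambi map distances, and
the split/trim heuristics used to consolidate groups over several mapping
rounds.

Genotype codes are integers throughout this module: 0 = ``a`` (homozygous
surface), 1 = ``h`` (heterozygous), 2 = ``b`` (homozygous cave), -1 = missing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import lsq_linear
from scipy.sparse.csgraph import connected_components

LN10 = math.log(10.0)

# ---------------------------------------------------------------------------
# Kosambi map function
# ---------------------------------------------------------------------------


def kosambi_cM(r, cap: float | None = None):
    """Kosambi map distance in centimorgans: d = 25 * ln((1+2r)/(1-2r)).

    Parameters
    ----------
    r : float or array-like
        Recombination fraction, 0 <= r < 0.5.
    cap : float, optional
        If given, fractions >= 0.5 map to this distance instead of raising.
    """
    r = np.asarray(r, dtype=float)
    bad = r >= 0.5
    if np.any(bad) and cap is None:
        raise ValueError("recombination fraction must be < 0.5 (or pass cap=)")
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5]")
    safe = np.where(bad, 0.25, r)
    d = 25.0 * np.log((1 + 2 * safe) / (1 - 2 * safe))
    if cap is not None:
        d = np.where(bad, cap, d)
    if d.ndim == 0:
        return float(d)
    return d


def kosambi_inverse(d):
    """Inverse Kosambi map function: r = 0.5 * tanh(d / 50) for d in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * np.tanh(d / 50.0)
    if r.ndim == 0:
        return float(r)
    return r


# ---------------------------------------------------------------------------
# Two-point statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseLinkage:
    """Two-point statistics for one marker pair.

    ``rf_hat`` is the maximum-likelihood recombination fraction (clipped to
    [0, 0.5]); ``linkage_lod`` compares r-hat with r = 0.5; the
    ``independence_lod`` is G2/(2 ln 10) from the 3x3 independence test on the
    joint genotype table and is robust to segregation distortion.
    """

    marker_i: str
    marker_j: str
    rf_hat: float
    linkage_lod: float
    independence_lod: float
    n_informative: int


def _joint_cell_logprobs(r):
    """Log of the nine F2 joint genotype probabilities, coupling phase.

    Returns an array of shape ``r.shape + (3, 3)`` indexed [geno_i, geno_j].
    """
    r = np.asarray(r, dtype=float)
    p, q = r, 1.0 - r
    cells = np.empty(r.shape + (3, 3))
    cells[..., 0, 0] = q**2 / 4
    cells[..., 0, 1] = p * q / 2
    cells[..., 0, 2] = p**2 / 4
    cells[..., 1, 0] = p * q / 2
    cells[..., 1, 1] = (p**2 + q**2) / 2
    cells[..., 1, 2] = p * q / 2
    cells[..., 2, 0] = p**2 / 4
    cells[..., 2, 1] = p * q / 2
    cells[..., 2, 2] = q**2 / 4
    return np.log(np.clip(cells, 1e-300, None))


def loglik_rf(r, table):
    """Log-likelihood of recombination fraction(s) ``r`` for 3x3 count table(s).

    ``r`` and ``table`` broadcast: shapes ``r.shape`` and ``table.shape[:-2]``
    must be compatible.
    """
    logp = _joint_cell_logprobs(r)
    table = np.asarray(table, dtype=float)
    terms = np.where(table > 0, table * logp, 0.0)
    return terms.sum(axis=(-2, -1))


def em_rf(tables, r0: float = 0.25, tol: float = 1e-8, max_iter: int = 200):
    """EM recombination-fraction estimates for a batch of 3x3 count tables.

    The double-heterozygote cell is a phase mixture: its expected number of
    recombinant gametes is ``2 r^2 / (r^2 + (1-r)^2)``; all other cells carry
    a known recombinant-gamete count.  Estimates are clipped to [0, 0.5].

    Parameters
    ----------
    tables : array (..., 3, 3) of counts.

    Returns
    -------
    rhat : array (...,) of ML recombination fractions (nan where the table is
        empty).
    """
    t = np.asarray(tables, dtype=float)
    n0 = t[..., 0, 0] + t[..., 2, 2]          # 0 recombinant gametes
    n2 = t[..., 0, 2] + t[..., 2, 0]          # 2 recombinant gametes
    n1 = t[..., 0, 1] + t[..., 1, 0] + t[..., 1, 2] + t[..., 2, 1]  # 1 each
    nh = t[..., 1, 1]                          # phase mixture
    n = n0 + n1 + n2 + nh
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.full(n.shape, r0, dtype=float)
        active = n > 0
        for _ in range(max_iter):
            p2 = r**2
            q2 = (1.0 - r) ** 2
            w = p2 / (p2 + q2)
            r_new = (n1 + 2.0 * n2 + 2.0 * nh * w) / (2.0 * n)
            r_new = np.clip(r_new, 0.0, 0.5)
            moved = np.abs(r_new - r) >= tol
            r = np.where(active, r_new, r)
            active = active & moved
            if not active.any():
                break
    return np.where(n > 0, r, np.nan)


def _g2_independence(tables):
    """G2 statistic of the 3x3 independence test for a batch of tables."""
    t = np.asarray(tables, dtype=float)
    n = t.sum(axis=(-2, -1))
    rows = t.sum(axis=-1)
    cols = t.sum(axis=-2)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = rows[..., :, None] * cols[..., None, :] / n[..., None, None]
        ratio = np.where((t > 0) & (expected > 0), t / expected, 1.0)
        g2 = 2.0 * np.where(t > 0, t * np.log(ratio), 0.0).sum(axis=(-2, -1))
    return np.where(n > 0, np.maximum(g2, 0.0), np.nan)


def joint_table(codes_i, codes_j) -> np.ndarray:
    """3x3 joint genotype count table for two code vectors (missing dropped)."""
    ci = np.asarray(codes_i)
    cj = np.asarray(codes_j)
    keep = (ci >= 0) & (cj >= 0)
    table = np.zeros((3, 3))
    np.add.at(table, (ci[keep], cj[keep]), 1.0)
    return table


def estimate_rf_em(codes_i, codes_j, marker_i: str = "i", marker_j: str = "j") -> PairwiseLinkage:
    """Two-point statistics for one pair of genotype-code vectors.

    Individuals missing either call are dropped; fewer than two complete
    pairs raises ``ValueError`` (such pairs are excluded from grouping).
    """
    table = joint_table(codes_i, codes_j)
    n = int(table.sum())
    if n < 2:
        raise ValueError(
            f"pair ({marker_i}, {marker_j}): fewer than 2 complete genotype pairs"
        )
    rhat = float(em_rf(table))
    lod = float((loglik_rf(rhat, table) - loglik_rf(0.5, table)) / LN10)
    ind = float(_g2_independence(table) / (2.0 * LN10))
    return PairwiseLinkage(
        marker_i, marker_j, rhat, max(lod, 0.0), max(ind, 0.0), n
    )


def pairwise_linkage_matrix(codes: np.ndarray):
    """All-pairs two-point statistics for a marker-by-individual code matrix.

    Parameters
    ----------
    codes : int array (m, n) with entries in {0, 1, 2, -1}.

    Returns
    -------
    rf, linkage_lod, independence_lod, n_informative : (m, m) arrays.
        Diagonals are 0 (rf), 0 (LODs).  Pairs with < 2 informative
        individuals hold nan rf and 0 LOD.
    """
    codes = np.asarray(codes)
    m, n = codes.shape
    indic = np.stack([(codes == g).astype(np.float64) for g in range(3)])  # (3, m, n)
    # tables[i, j, gi, gj] = number of individuals with genotypes (gi, gj)
    tables = np.einsum("gmn,hkn->mkgh", indic, indic)
    counts = tables.sum(axis=(-2, -1))
    rf = em_rf(tables)
    lod = (loglik_rf(rf, tables) - loglik_rf(np.full(rf.shape, 0.5), tables)) / LN10
    ind = _g2_independence(tables) / (2.0 * LN10)
    few = counts < 2
    rf[few] = np.nan
    lod = np.where(few, 0.0, np.maximum(lod, 0.0))
    ind = np.where(few, 0.0, np.maximum(ind, 0.0))
    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(ind, 0.0)
    return rf, lod, ind, counts.astype(int)


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


def group_markers(independence_lod: np.ndarray, threshold: float) -> list[list[int]]:
    """Single-linkage partition: connected components of LOD >= threshold.

    Returns member index lists, largest group first (ties by smallest member
    index).
    """
    if threshold <= 0:
        raise ValueError("grouping threshold must be > 0")
    adj = sparse.csr_matrix(independence_lod >= threshold)
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(idx)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


def threshold_ladder(independence_lod: np.ndarray, max_lod: int = 50) -> dict[int, list[list[int]]]:
    """Partitions at each integer independence-LOD threshold 1..max_lod."""
    return {t: group_markers(independence_lod, t) for t in range(1, max_lod + 1)}


def split_group(members: list[int], independence_lod: np.ndarray,
                min_markers: int, max_lod: int = 50):
    """Split a group at the lowest integer LOD giving two parts of >= min_markers.

    Scans the threshold ladder upward over the subgraph induced by ``members``
    and returns ``(parts, threshold, split_flag)``; if no threshold yields
    exactly two connected components each of size >= ``min_markers`` the group
    is returned unchanged with ``split_flag=False``.
    """
    sub = independence_lod[np.ix_(members, members)]
    for t in range(1, max_lod + 1):
        comps = group_markers(sub, t)
        if len(comps) == 2 and all(len(c) >= min_markers for c in comps):
            parts = [[members[i] for i in comp] for comp in comps]
            return parts, t, True
        if len(comps) > 2:
            break
    return [list(members)], None, False


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------


@dataclass
class LinkageGroup:
    """An ordered linkage group: markers with cM positions starting at 0."""

    group_id: str
    markers: list[str]
    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.markers) != len(self.positions):
            raise ValueError("markers and positions length mismatch")
        if len(self.positions) and abs(self.positions[0]) > 1e-9:
            raise ValueError("positions must start at 0")
        if np.any(np.diff(self.positions) < -1e-9):
            raise ValueError("positions must be nondecreasing")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def length_cM(self) -> float:
        return float(self.positions[-1]) if self.n_markers else 0.0

    @property
    def mean_intermarker_cM(self) -> float:
        """Mean adjacent gap = length / (n - 1); nan for single-marker groups."""
        if self.n_markers < 2:
            return float("nan")
        return self.length_cM / (self.n_markers - 1)


@dataclass
class GeneticMap:
    groups: list[LinkageGroup] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    @property
    def total_length_cM(self) -> float:
        return float(sum(g.length_cM for g in self.groups))

    @property
    def density_per_cM(self) -> float:
        """Marker density = total markers / total map length."""
        total = self.total_length_cM
        return self.n_markers / total if total > 0 else float("nan")


def _order_criterion(order, rf, lod, rf_max=0.4):
    """Weighted least-squares score of a candidate order.

    Positions come from cumulative adjacent Kosambi distances; the score sums
    ``lod_ij * (|x_i - x_j| - kosambi(rf_ij))^2`` over pairs with rf < rf_max.
    """
    idx = np.asarray(order)
    r_adj = np.clip(rf[idx[:-1], idx[1:]], 0.0, 0.4999)
    x = np.concatenate([[0.0], np.cumsum(kosambi_cM(r_adj))])
    sub_rf = rf[np.ix_(idx, idx)]
    sub_lod = lod[np.ix_(idx, idx)]
    mask = np.triu(np.isfinite(sub_rf) & (sub_rf < rf_max), k=1)
    d_obs = kosambi_cM(np.clip(sub_rf, 0.0, 0.4999))
    d_pos = np.abs(x[:, None] - x[None, :])
    return float((sub_lod * (d_pos - d_obs) ** 2)[mask].sum())


def _fit_positions(order, rf, lod, rf_max=0.4):
    """Final cM positions: nonnegative adjacent gaps fitted by weighted LS.

    Every pair with rf < rf_max contributes the constraint
    "sum of spanned gaps = kosambi(rf)" with weight = linkage LOD; seeded from
    cumulative adjacent distances when the system is degenerate.
    """
    idx = np.asarray(order)
    m = len(idx)
    if m == 1:
        return np.zeros(1)
    rows, dists, weights = [], [], []
    sub_rf = rf[np.ix_(idx, idx)]
    sub_lod = lod[np.ix_(idx, idx)]
    for i in range(m - 1):
        for j in range(i + 1, m):
            r = sub_rf[i, j]
            if not np.isfinite(r) or r >= rf_max:
                continue
            w = sub_lod[i, j]
            if w <= 0:
                continue
            row = np.zeros(m - 1)
            row[i:j] = 1.0
            rows.append(row)
            dists.append(kosambi_cM(min(r, 0.4999)))
            weights.append(w)
    r_adj = np.clip(sub_rf[np.arange(m - 1), np.arange(1, m)], 0.0, 0.4999)
    fallback = kosambi_cM(r_adj)
    if not rows:
        gaps = fallback
    else:
        a = np.asarray(rows)
        sw = np.sqrt(np.asarray(weights))
        res = lsq_linear(a * sw[:, None], np.asarray(dists) * sw, bounds=(0.0, np.inf))
        gaps = res.x
    return np.concatenate([[0.0], np.cumsum(gaps)])


def order_group(marker_ids, members, rf, lod, rf_max=0.4, polish_passes=10) -> LinkageGroup:
    """Order one linkage group by incremental insertion plus local polish.

    Seeds with the most-informative pair (highest linkage LOD), repeatedly
    inserts the unplaced marker with the strongest linkage to the current
    order at the position minimizing the weighted least-squares criterion, and
    polishes with sliding-window permutations of width 3 until no improvement.
    Orientation is canonicalized so the lexicographically smaller terminal
    marker comes first.
    """
    members = list(members)
    if len(members) == 1:
        return LinkageGroup("", [marker_ids[members[0]]], np.zeros(1))
    sub_lod = lod[np.ix_(members, members)].copy()
    np.fill_diagonal(sub_lod, -np.inf)
    # seed: most-informative pair, deterministic tie-break by marker id
    best = np.unravel_index(np.argmax(sub_lod), sub_lod.shape)
    order = [members[best[0]], members[best[1]]]
    order.sort(key=lambda k: marker_ids[k])
    remaining = [m for m in members if m not in order]
    while remaining:
        strengths = [(max(lod[m, o] for o in order), marker_ids[m]) for m in remaining]
        pick = remaining[int(np.lexsort(([s[1] for s in strengths],
                                         [-s[0] for s in strengths]))[0])]
        remaining.remove(pick)
        scores = []
        for slot in range(len(order) + 1):
            cand = order[:slot] + [pick] + order[slot:]
            scores.append(_order_criterion(cand, rf, lod, rf_max))
        slot = int(np.argmin(scores))
        order = order[:slot] + [pick] + order[slot:]
        order = _polish(order, rf, lod, rf_max, max_passes=1)
    order = _polish(order, rf, lod, rf_max, max_passes=polish_passes)
    # canonical orientation
    if marker_ids[order[-1]] < marker_ids[order[0]]:
        order = order[::-1]
    positions = _fit_positions(order, rf, lod, rf_max)
    return LinkageGroup("", [marker_ids[k] for k in order], positions)


def _polish(order, rf, lod, rf_max, max_passes=10):
    """Sliding-window (width 3) permutation polish; accepts improvements only."""
    order = list(order)
    if len(order) < 3:
        return order
    best_score = _order_criterion(order, rf, lod, rf_max)
    for _ in range(max_passes):
        improved = False
        for start in range(len(order) - 2):
            window = order[start:start + 3]
            for perm in itertools.permutations(window):
                if list(perm) == window:
                    continue
                cand = order[:start] + list(perm) + order[start + 3:]
                score = _order_criterion(cand, rf, lod, rf_max)
                if score < best_score - 1e-12:
                    order, best_score, improved = cand, score, True
        if not improved:
            break
    return order


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------


def trim_distal(group: LinkageGroup, gap_factor: float = 3.0,
                min_gap_cM: float = 10.0):
    """Iteratively drop terminal markers beyond sparse distal gaps.

    A terminal marker is removed when its gap to the neighbor exceeds
    ``max(min_gap_cM, gap_factor * mean intermarker distance)``; the rule is
    re-evaluated until stable.  Returns ``(trimmed_group, removed_ids)``.
    """
    markers = list(group.markers)
    pos = np.asarray(group.positions, dtype=float).copy()
    removed: list[str] = []
    while len(markers) >= 2:
        gaps = np.diff(pos)
        mean_gap = (pos[-1] - pos[0]) / (len(markers) - 1)
        cut = max(min_gap_cM, gap_factor * mean_gap)
        if gaps[0] > cut:
            removed.append(markers.pop(0))
            pos = pos[1:] - pos[1]
        elif gaps[-1] > cut:
            removed.append(markers.pop())
            pos = pos[:-1]
        else:
            break
    return LinkageGroup(group.group_id, markers, pos - pos[0] if len(pos) else pos), removed


# ---------------------------------------------------------------------------
# Map-building protocol
# ---------------------------------------------------------------------------


@dataclass
class MapProtocol:
    """Configuration for the multi-round map-building heuristic."""

    grouping_lod: float | None = None     # None -> auto-select from the ladder
    grouping_lod_max: int = 50
    rounds: int = 3
    min_group_size: int = 10
    max_mean_spacing_cM: float = 4.0
    split_min_markers: tuple[int, ...] = (20, 10)
    split_size_factor: float = 1.5     # only groups >= factor x median size
    trim_gap_factor: float = 3.0
    trim_min_gap_cM: float = 10.0
    rf_max: float = 0.4


def _auto_threshold(independence_lod, min_size, max_lod):
    """Pick the grouping threshold from the ladder's most stable plateau.

    The count of groups with >= min_size markers rises as fused chromosomes
    separate, plateaus at the true chromosome number, then rises again when
    chains fragment at very high thresholds.  The longest run of constant
    count identifies the stable regime; its lowest threshold is returned
    (ties broken toward the higher count, then the lower threshold).
    """
    counts = []
    for t in range(1, max_lod + 1):
        groups = group_markers(independence_lod, t)
        counts.append(sum(1 for g in groups if len(g) >= min_size))
    runs = []           # (length, count, first_t)
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            runs.append((i - start, counts[start], start + 1))
            start = i
    viable = [r for r in runs if r[1] > 0]
    if not viable:
        return 1
    viable.sort(key=lambda r: (-r[0], -r[1], r[2]))
    return viable[0][2]


def build_map(marker_ids, codes, protocol: MapProtocol | None = None):
    """Build a genetic map from retained coded markers.

    Parameters
    ----------
    marker_ids : sequence of str, length m.
    codes : int array (m, n_individuals), entries in {0, 1, 2, -1}.
    protocol : MapProtocol, optional.

    Returns
    -------
    genetic_map : GeneticMap (groups sorted by descending size, ids LG1..).
    audit : list of dict — every grouping threshold, elimination, split and
        trim event, in order.
    """
    protocol = protocol or MapProtocol()
    marker_ids = list(marker_ids)
    codes = np.asarray(codes)
    rf, lod, ind, _ = pairwise_linkage_matrix(codes)
    audit: list[dict] = []

    threshold = protocol.grouping_lod
    if threshold is None:
        threshold = _auto_threshold(ind, protocol.min_group_size,
                                    protocol.grouping_lod_max)
    audit.append({"event": "grouping", "threshold": threshold})
    member_groups = group_markers(ind, threshold)
    groups = [order_group(marker_ids, g, rf, lod, protocol.rf_max)
              for g in member_groups]
    index_of = {mid: k for k, mid in enumerate(marker_ids)}

    for rnd in range(1, protocol.rounds + 1):
        # drop small or sparse groups
        kept = []
        for g in groups:
            if g.n_markers < protocol.min_group_size:
                audit.append({"event": "drop_group", "round": rnd,
                              "reason": "too_few_markers",
                              "markers": list(g.markers)})
            elif g.n_markers >= 2 and g.mean_intermarker_cM > protocol.max_mean_spacing_cM:
                audit.append({"event": "drop_group", "round": rnd,
                              "reason": "sparse",
                              "mean_spacing": g.mean_intermarker_cM,
                              "markers": list(g.markers)})
            else:
                kept.append(g)
        groups = kept
        if not groups:
            raise RuntimeError("no linkage groups survive the protocol")

        # split unusually large groups (likely fusions of two chromosomes)
        # at the lowest workable ladder threshold
        if rnd <= len(protocol.split_min_markers):
            min_markers = protocol.split_min_markers[rnd - 1]
            median_size = float(np.median([g.n_markers for g in groups]))
            size_cut = protocol.split_size_factor * median_size
            new_groups = []
            for g in groups:
                members = [index_of[m] for m in g.markers]
                if len(members) >= 2 * min_markers and len(members) >= size_cut:
                    parts, t, did = split_group(members, ind, min_markers,
                                                protocol.grouping_lod_max)
                    if did:
                        audit.append({"event": "split", "round": rnd,
                                      "threshold": t,
                                      "sizes": [len(p) for p in parts]})
                        for part in parts:
                            new_groups.append(order_group(marker_ids, part, rf,
                                                          lod, protocol.rf_max))
                        continue
                new_groups.append(g)
            groups = new_groups

        # trim sparse distal ends, then re-order what changed
        trimmed = []
        for g in groups:
            g2, removed = trim_distal(g, protocol.trim_gap_factor,
                                      protocol.trim_min_gap_cM)
            if removed:
                audit.append({"event": "trim", "round": rnd,
                              "markers": removed})
                members = [index_of[m] for m in g2.markers]
                g2 = order_group(marker_ids, members, rf, lod, protocol.rf_max)
            trimmed.append(g2)
        groups = trimmed

    groups.sort(key=lambda g: (-g.n_markers, g.markers[0]))
    for k, g in enumerate(groups, start=1):
        g.group_id = f"LG{k}"
    gmap = GeneticMap(groups)
    placed = {m for g in groups for m in g.markers}
    audit.append({"event": "final", "placed": len(placed),
                  "eliminated": len(marker_ids) - len(placed)})
    return gmap, audit


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def mean_intermarker(n_markers: int, length_cM: float) -> float:
    """Mean intermarker distance of one group: length / (n - 1)."""
    if n_markers < 2:
        return float("nan")
    return length_cM / (n_markers - 1)


def marker_density(n_markers: int, total_length_cM: float) -> float:
    """Map-wide marker density in markers per cM, rounded to 2 decimals."""
    return round(n_markers / total_length_cM, 2)


def map_summary(genetic_map: GeneticMap) -> dict:
    """Per-group and map-total summary statistics.

    The map-wide mean intermarker distance is reported under two candidate
    definitions (mean of per-group means, and total length / (markers -
    groups)) since neither is canonical.
    """
    per_group = [
        {
            "group": g.group_id,
            "n_markers": g.n_markers,
            "length_cM": g.length_cM,
            "mean_intermarker_cM": g.mean_intermarker_cM,
        }
        for g in genetic_map.groups
    ]
    n = genetic_map.n_markers
    total = genetic_map.total_length_cM
    n_groups = len(genetic_map.groups)
    group_means = [g["mean_intermarker_cM"] for g in per_group
                   if not math.isnan(g["mean_intermarker_cM"])]
    return {
        "per_group": per_group,
        "n_groups": n_groups,
        "n_markers": n,
        "total_length_cM": total,
        "density_per_cM": marker_density(n, total) if total > 0 else float("nan"),
        "mean_intermarker_of_group_means": (
            float(np.mean(group_means)) if group_means else float("nan")
        ),
        "mean_intermarker_pooled": (
            total / (n - n_groups) if n > n_groups else float("nan")
        ),
    }
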