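"""Single-QTL genome scan for a binary trait in an F2 intercross.

The 0/1 phenotype is analyzed under the Gaussian working model (the standard
scan for a numerically coded binary trait), with three methods: marker
regression (MR) on observed genotypes at typed markers, Haley-Knott (HK)
regression on conditional genotype probabilities at every grid position, and
EM interval mapping (a three-component Gaussian mixture with class weights
from the genotype-probability grid).  Genotype probabilities come from a
forward-backward pass over a Markov chain on {SS, SC, CC} whose transition
matrices derive from the Kosambi inverse of inter-position distances, with a
symmetric genotyping-error emission parameter epsilon.

Genome-wide significance thresholds are empirical quantiles of the maximum
LOD over phenotype permutations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cavemap.linkage import GeneticMap, kosambi_inverse

LOG10 = np.log(10.0)
_SIGMA2_FLOOR = 1e-4   # residual-variance floor on the 0/1 phenotype scale
_RSS_FLOOR = 1e-12


@dataclass
class GenotypeProbGrid:
    """Conditional genotype probabilities on an evaluation grid.

    ``positions``: DataFrame with columns group, pos_cM, marker (None between
    markers).  ``probs``: array (n_positions, n_individuals, 3) of P(SS),
    P(SC), P(CC).  ``marker_codes``: observed integer codes (-1 missing) at
    typed positions, NaN-free only where ``marker`` is set.
    """

    positions: pd.DataFrame
    probs: np.ndarray
    epsilon: float
    marker_codes: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[1]


def _transition(r: float) -> np.ndarray:
    """F2 genotype transition matrix over one interval with recombination r."""
    p, q = r, 1.0 - r
    return np.array([
        [q * q, 2 * p * q, p * p],
        [p * q, p * p + q * q, p * q],
        [p * p, 2 * p * q, q * q],
    ])


def genotype_probs(genetic_map: GeneticMap, codes: pd.DataFrame,
                   step_cM: float = 1.0, epsilon: float = 0.001) -> GenotypeProbGrid:
    """Forward-backward genotype reconstruction on a cM grid.

    Parameters
    ----------
    genetic_map : ordered linkage groups with cM positions.
    codes : DataFrame (markers x individuals) of integer codes 0/1/2/-1.
    step_cM : grid step between markers; 0 evaluates at markers only.
    epsilon : per-call genotyping-error emission probability (correct class
        1 - epsilon, each other class epsilon / 2); missing calls emit
        uniformly.
    """
    if not 0 <= epsilon < 0.2:
        raise ValueError("epsilon must be in [0, 0.2)")
    if not genetic_map.groups:
        raise ValueError("empty genetic map")
    n_ind = codes.shape[1]
    prior = np.array([0.25, 0.5, 0.25])
    pos_rows = []
    prob_blocks = []
    marker_codes: dict[int, np.ndarray] = {}
    offset = 0
    for group in genetic_map.groups:
        grid, is_marker, marker_at = _build_grid(group, step_cM)
        n_pos = len(grid)
        emit = np.ones((n_pos, n_ind, 3))
        for p_idx, mid in marker_at.items():
            obs = codes.loc[mid].to_numpy().astype(int)
            e = np.full((n_ind, 3), epsilon / 2.0)
            e[np.arange(n_ind), np.clip(obs, 0, 2)] = 1.0 - epsilon
            e[obs < 0] = 1.0 / 3.0
            emit[p_idx] = e
        trans = [_transition(kosambi_inverse(d)) for d in np.diff(grid)]

        alpha = np.empty((n_pos, n_ind, 3))
        scale = np.empty((n_pos, n_ind))
        a = prior[None, :] * emit[0]
        scale[0] = a.sum(axis=1)
        alpha[0] = a / scale[0][:, None]
        for t in range(1, n_pos):
            a = (alpha[t - 1] @ trans[t - 1]) * emit[t]
            scale[t] = a.sum(axis=1)
            alpha[t] = a / scale[t][:, None]
        beta = np.empty_like(alpha)
        beta[-1] = 1.0
        for t in range(n_pos - 2, -1, -1):
            b = (beta[t + 1] * emit[t + 1]) @ trans[t].T
            beta[t] = b / scale[t + 1][:, None]
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)

        for p_idx in range(n_pos):
            mid = marker_at.get(p_idx)
            pos_rows.append({"group": group.group_id, "pos_cM": grid[p_idx],
                             "marker": mid})
            if mid is not None:
                marker_codes[offset + p_idx] = codes.loc[mid].to_numpy().astype(int)
        prob_blocks.append(post)
        offset += n_pos
    return GenotypeProbGrid(
        positions=pd.DataFrame(pos_rows),
        probs=np.concatenate(prob_blocks, axis=0),
        epsilon=epsilon,
        marker_codes=marker_codes,
    )


def _build_grid(group, step_cM):
    """Marker positions merged with an optional regular step grid."""
    marker_pos = np.asarray(group.positions, dtype=float)
    grid = list(marker_pos)
    if step_cM and step_cM > 0 and group.length_cM > 0:
        grid.extend(np.arange(0.0, group.length_cM, step_cM)[1:])
    grid = np.array(sorted(set(np.round(grid, 9))))
    marker_at = {}
    for mid, pos in zip(group.markers, marker_pos):
        idx = int(np.argmin(np.abs(grid - pos)))
        marker_at[idx] = mid
    is_marker = np.zeros(len(grid), dtype=bool)
    is_marker[list(marker_at)] = True
    return grid, is_marker, marker_at


# ---------------------------------------------------------------------------
# Scan methods
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    positions: pd.DataFrame              # group, pos_cM, marker
    lod: dict[str, np.ndarray]           # method -> LOD per position
    thresholds: dict[str, dict[float, float]] = field(default_factory=dict)

    def peak(self, method: str):
        """(position row, LOD) of the genome-wide maximum for one method."""
        scores = self.lod[method]
        idx = int(np.nanargmax(scores))
        return self.positions.iloc[idx], float(scores[idx])

    def frame(self) -> pd.DataFrame:
        out = self.positions.copy()
        for method, scores in self.lod.items():
            out[f"lod_{method}"] = scores
        return out


def _null_rss(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum())


def _mr_lod(y, codes):
    """One-way genotype-class regression LOD at a typed marker."""
    keep = codes >= 0
    ysub, csub = y[keep], codes[keep]
    n = len(ysub)
    if n == 0 or len(np.unique(csub)) < 2:
        return 0.0
    rss0 = _null_rss(ysub)
    rss1 = 0.0
    for g in np.unique(csub):
        cls = ysub[csub == g]
        rss1 += float(((cls - cls.mean()) ** 2).sum())
    if rss0 <= _RSS_FLOOR:
        return 0.0
    return (n / 2.0) * np.log10(rss0 / max(rss1, _RSS_FLOOR))


def _hk_design(weights: np.ndarray) -> np.ndarray:
    # intercept + P(SC) + P(CC); P(SS) is the omitted reference class
    return np.column_stack([np.ones(len(weights)), weights[:, 1], weights[:, 2]])


def _hk_lod(y, weights):
    n = len(y)
    x = _hk_design(weights)
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    rss1 = float(((y - x @ coef) ** 2).sum())
    rss0 = _null_rss(y)
    if rss0 <= _RSS_FLOOR:
        return 0.0
    return (n / 2.0) * np.log10(rss0 / max(rss1, _RSS_FLOOR))


def _gaussian_ll(y, mu, sigma2):
    return -0.5 * len(y) * np.log(2 * np.pi * sigma2) \
        - 0.5 * ((y - mu) ** 2).sum() / sigma2


def _em_lod(y, weights, tol=1e-6, max_iter=100):
    """EM interval-mapping LOD: 3-component Gaussian mixture with fixed
    mixing weights per individual."""
    n = len(y)
    certain = weights.max(axis=1) > 1.0 - 1e-9
    if certain.all():
        # complete certainty: the mixture degenerates to the HK regression
        return _hk_lod(y, weights)
    rss0 = _null_rss(y)
    if rss0 <= _RSS_FLOOR:
        return 0.0
    sigma2_0 = rss0 / n
    ll0 = _gaussian_ll(y, y.mean(), sigma2_0)

    x = _hk_design(weights)
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    mu = np.array([coef[0], coef[0] + coef[1], coef[0] + coef[2]])
    resid = y - x @ coef
    sigma2 = max(float((resid**2).mean()), _SIGMA2_FLOOR)

    ll_old = -np.inf
    for _ in range(max_iter):
        dens = np.exp(-0.5 * (y[:, None] - mu[None, :]) ** 2 / sigma2) \
            / np.sqrt(2 * np.pi * sigma2)
        num = weights * dens
        tot = num.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        resp = num / tot[:, None]
        ll = float(np.log(tot).sum())
        wsum = resp.sum(axis=0)
        mu = np.where(wsum > 1e-12, (resp * y[:, None]).sum(axis=0) / np.maximum(wsum, 1e-12), mu)
        sigma2 = float((resp * (y[:, None] - mu[None, :]) ** 2).sum() / n)
        sigma2 = max(sigma2, _SIGMA2_FLOOR)
        if ll - ll_old < tol:
            break
        ll_old = ll
    return max((ll - ll0) / LOG10, 0.0)


def scanone(phenotypes, grid: GenotypeProbGrid,
            methods=("mr", "em", "hk")) -> ScanResult:
    """Genome scan of a binary (0/1) phenotype over the genotype grid.

    MR is defined only at typed markers (NaN elsewhere); HK and EM score
    every grid position.  A constant phenotype yields all-zero LOD with a
    warning.
    """
    y = np.asarray(phenotypes, dtype=float)
    if len(y) != grid.n_individuals:
        raise ValueError("phenotype length does not match cohort size")
    constant = len(np.unique(y)) < 2
    if constant:
        warnings.warn("constant phenotype: all LOD scores are zero")
    lods: dict[str, np.ndarray] = {}
    for method in methods:
        scores = np.zeros(grid.n_positions)
        if method == "mr":
            scores = np.full(grid.n_positions, np.nan)
            for p_idx, obs in grid.marker_codes.items():
                scores[p_idx] = 0.0 if constant else _mr_lod(y, obs)
        elif method == "hk":
            if not constant:
                for p_idx in range(grid.n_positions):
                    scores[p_idx] = _hk_lod(y, grid.probs[p_idx])
        elif method == "em":
            if not constant:
                for p_idx in range(grid.n_positions):
                    scores[p_idx] = _em_lod(y, grid.probs[p_idx])
        else:
            raise ValueError(f"unknown scan method: {method}")
        lods[method] = scores
    return ScanResult(positions=grid.positions.copy(), lod=lods)


# ---------------------------------------------------------------------------
# Permutation thresholds
# ---------------------------------------------------------------------------


def _max_lod_batch(Y: np.ndarray, grid: GenotypeProbGrid, method: str):
    """Genome-wide maximum LOD per permuted phenotype column (vectorized)."""
    n, n_perm = Y.shape
    best = np.full(n_perm, -np.inf)
    if method == "mr":
        for p_idx, obs in grid.marker_codes.items():
            keep = obs >= 0
            ysub = Y[keep]
            csub = obs[keep]
            nsub = keep.sum()
            if nsub == 0 or len(np.unique(csub)) < 2:
                continue
            x = np.zeros((nsub, 3))
            x[np.arange(nsub), csub] = 1.0
            x = x[:, np.unique(csub)]
            q, _ = np.linalg.qr(x)
            ss = (ysub**2).sum(axis=0)
            rss0 = ss - nsub * ysub.mean(axis=0) ** 2
            rss1 = ss - ((q.T @ ysub) ** 2).sum(axis=0)
            lod = (nsub / 2.0) * np.log10(
                np.maximum(rss0, _RSS_FLOOR) / np.maximum(rss1, _RSS_FLOOR))
            lod[rss0 <= _RSS_FLOOR] = 0.0
            best = np.maximum(best, lod)
    elif method == "hk":
        ss = (Y**2).sum(axis=0)
        rss0 = ss - n * Y.mean(axis=0) ** 2
        for p_idx in range(grid.n_positions):
            q, _ = np.linalg.qr(_hk_design(grid.probs[p_idx]))
            rss1 = ss - ((q.T @ Y) ** 2).sum(axis=0)
            lod = (n / 2.0) * np.log10(
                np.maximum(rss0, _RSS_FLOOR) / np.maximum(rss1, _RSS_FLOOR))
            lod[rss0 <= _RSS_FLOOR] = 0.0
            best = np.maximum(best, lod)
    elif method == "em":
        for p_idx in range(grid.n_positions):
            lod = _em_lod_batch(Y, grid.probs[p_idx])
            best = np.maximum(best, lod)
    else:
        raise ValueError(f"unknown scan method: {method}")
    return best


def _em_lod_batch(Y: np.ndarray, weights: np.ndarray, tol=1e-6, max_iter=60):
    """EM LOD for many phenotype columns at one position, batched."""
    n, n_perm = Y.shape
    certain = weights.max(axis=1) > 1.0 - 1e-9
    ss = (Y**2).sum(axis=0)
    ybar = Y.mean(axis=0)
    rss0 = ss - n * ybar**2
    if certain.all():
        q, _ = np.linalg.qr(_hk_design(weights))
        rss1 = ss - ((q.T @ Y) ** 2).sum(axis=0)
        lod = (n / 2.0) * np.log10(
            np.maximum(rss0, _RSS_FLOOR) / np.maximum(rss1, _RSS_FLOOR))
        lod[rss0 <= _RSS_FLOOR] = 0.0
        return lod
    sigma2_0 = np.maximum(rss0 / n, _RSS_FLOOR)
    ll0 = -0.5 * n * np.log(2 * np.pi * sigma2_0) - 0.5 * rss0 / sigma2_0

    x = _hk_design(weights)
    coef, _, _, _ = np.linalg.lstsq(x, Y, rcond=None)       # (3, n_perm)
    mu = np.vstack([coef[0], coef[0] + coef[1], coef[0] + coef[2]])  # (3, P)
    resid = Y - x @ coef
    sigma2 = np.maximum((resid**2).mean(axis=0), _SIGMA2_FLOOR)      # (P,)

    ll = np.full(n_perm, -np.inf)
    active = np.ones(n_perm, dtype=bool)
    W = weights[:, None, :]                                 # (n, 1, 3)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Ya = Y[:, idx]
        mua = mu[:, idx]
        s2 = sigma2[idx]
        diff = Ya[:, :, None] - mua.T[None, :, :]           # (n, p, 3)
        dens = np.exp(-0.5 * diff**2 / s2[None, :, None]) \
            / np.sqrt(2 * np.pi * s2)[None, :, None]
        num = W * dens
        tot = np.maximum(num.sum(axis=2), 1e-300)           # (n, p)
        resp = num / tot[:, :, None]
        ll_new = np.log(tot).sum(axis=0)
        wsum = resp.sum(axis=0)                             # (p, 3)
        mu_new = np.where(wsum > 1e-12,
                          (resp * Ya[:, :, None]).sum(axis=0) / np.maximum(wsum, 1e-12),
                          mua.T)
        diff2 = Ya[:, :, None] - mu_new[None, :, :]
        s2_new = np.maximum((resp * diff2**2).sum(axis=(0, 2)) / n, _SIGMA2_FLOOR)
        mu[:, idx] = mu_new.T
        sigma2[idx] = s2_new
        done = ll_new - ll[idx] < tol
        ll[idx] = ll_new
        active[idx[done]] = False
    return np.maximum((ll - ll0) / LOG10, 0.0)


def permutation_threshold(phenotypes, grid: GenotypeProbGrid, method: str,
                          n_perm: int = 1000, alphas=(0.05, 0.001),
                          seed: int = 0) -> dict[float, float]:
    """Genome-wide permutation thresholds for one scan method.

    Permutes phenotype labels ``n_perm`` times, records the genome-wide
    maximum LOD per permutation, and returns the empirical (1 - alpha)
    quantiles.  Requires ``n_perm >= 1 / min(alphas)``.
    """
    alphas = tuple(alphas)
    if n_perm < 1.0 / min(alphas):
        raise ValueError(
            f"n_perm={n_perm} too small for alpha={min(alphas)} "
            f"(need >= {math.ceil(1.0 / min(alphas))})")
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotypes, dtype=float)
    Y = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    maxima = _max_lod_batch(Y, grid, method)
    return {
        alpha: float(np.quantile(maxima, 1.0 - alpha, method="higher"))
        for alpha in alphas
    }


# ---------------------------------------------------------------------------
# Effect summaries
# ---------------------------------------------------------------------------

_CLASS_NAMES = ("SS", "SC", "CC")


def effect_summary(marker_codes, phenotypes) -> pd.DataFrame:
    """Per-genotype-class phenotype count, mean and standard error at a marker."""
    codes = np.asarray(marker_codes, dtype=int)
    y = np.asarray(phenotypes, dtype=float)
    rows = []
    for g, name in enumerate(_CLASS_NAMES):
        cls = y[codes == g]
        n = len(cls)
        mean = float(cls.mean()) if n else float("nan")
        se = float(cls.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append({"genotype": name, "n": n, "mean": mean, "se": se})
    return pd.DataFrame(rows).set_index("genotype")
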