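"""Independent brute-force oracles used by unit and acceptance tests.

These re-derive expected values along a different computational path from
the implementation they check (grid search instead of EM; an explicit
decision table instead of the resolver's control flow; direct pair counting
instead of the tie-adjusted statistic).
"""

import itertools
from collections import namedtuple

import numpy as np

Hit = namedtuple("Hit", "target evalue pident length sstart send")


def grid_search_rf(table, step=1e-4):
    """ML recombination fraction by brute-force likelihood grid search.

    The F2 joint genotype probabilities are written out directly here
    (coupling phase): P(aa)=P(bb)=q^2/4, P(ab)=P(ba)=p^2/4, single-het cells
    pq/2, double het (p^2+q^2)/2, with p=r, q=1-r.
    """
    table = np.asarray(table, dtype=float)
    grid = np.arange(0.0, 0.5 + step / 2, step)
    p = grid
    q = 1.0 - grid
    probs = np.empty((len(grid), 3, 3))
    probs[:, 0, 0] = probs[:, 2, 2] = q * q / 4
    probs[:, 0, 2] = probs[:, 2, 0] = p * p / 4
    probs[:, 0, 1] = probs[:, 1, 0] = probs[:, 1, 2] = probs[:, 2, 1] = p * q / 2
    probs[:, 1, 1] = (p * p + q * q) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(table[None] > 0,
                      table[None] * np.log(probs), 0.0).sum(axis=(1, 2))
    return float(grid[np.argmax(ll)])


def _chain(hit):
    return (hit.evalue, -hit.pident, -hit.length, hit.sstart, hit.send)


def resolve_oracle(hits, support):
    """Hand-specified decision table for hit resolution.

    ``hits``: post-collapse hits for one marker (distinct targets).
    ``support``: set of supported target ids for the marker's linkage group.
    Returns ``(retained_target_or_None, category)``.
    """
    hits = list(hits)
    if len(hits) == 1:
        return hits[0].target, "single_robust"
    best_e = min(h.evalue for h in hits)
    e_tied = [h for h in hits if h.evalue == best_e]
    best_p = max(h.pident for h in e_tied)
    top_set = [h for h in e_tied if h.pident == best_p]
    supported = sorted((h for h in hits if h.target in support), key=_chain)
    if len({h.target for h in top_set}) == 1:
        top = min(top_set, key=_chain)
        if top.target in support:
            return top.target, "top_supported"
        if supported:
            return supported[0].target, "not_top_supported"
        return top.target, "top_unsupported"
    # top hit undeterminable: e-value and identity tied across targets
    tied_supported = sorted((h for h in top_set if h.target in support),
                            key=_chain)
    if tied_supported:
        return tied_supported[0].target, "top_supported"
    if supported:
        return supported[0].target, "not_top_supported"
    return None, "unresolved"


def enumerate_resolver_cases():
    """All configurations of <= 3 distinct-target hits x <= 2 support targets.

    E-values and identities are drawn from two-level sets so every tie
    pattern (including full top-hit ambiguity) is exercised.
    """
    targets = ["T1", "T2", "T3"]
    evalues = [1e-20, 1e-5]
    pidents = [98.0, 90.0]
    supports = [set(), {"T1"}, {"T2"}, {"T3"}, {"T1", "T2"}, {"T1", "T3"},
                {"T2", "T3"}]
    cases = []
    for n in (1, 2, 3):
        used = targets[:n]
        for combo in itertools.product(itertools.product(evalues, pidents),
                                       repeat=n):
            hits = [Hit(t, e, p, 60, 100 + 10 * k, 160 + 10 * k)
                    for k, (t, (e, p)) in enumerate(zip(used, combo))]
            for support in supports:
                cases.append((hits, support))
    return cases


def kendall_brute_force(x, y):
    """Kendall tau-b by direct concordant/discordant pair counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[j] - x[i])
            dy = np.sign(y[j] - y[i])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom if denom else float("nan")
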