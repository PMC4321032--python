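"""Anchoring draft-genome scaffolds onto the linkage map.

Each scaffold is assigned the modal linkage group of its mapped markers;
colocalization measures how often all of a scaffold's markers fall on a
single group, and colinearity is the Kendall rank correlation between
scaffold bp order and linkage-group cM order (orientation from its sign).
Map-comparison ratios express one map's metrics as integer percentages of
another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau


@dataclass
class ScaffoldAnchor:
    scaffold: str
    group: str | None                   # None when the modal group is tied
    n_markers: int
    pairs: pd.DataFrame                 # marker, pos_bp, pos_cM, group
    colocalized: bool
    tau: float                          # nan for < 2 usable markers
    orientation: str                    # forward / reverse / ambiguous


def colinearity(pairs: pd.DataFrame) -> tuple[float, str]:
    """Tie-adjusted Kendall tau between bp and cM order, plus orientation."""
    bp = pairs["pos_bp"].to_numpy(dtype=float)
    cm = pairs["pos_cM"].to_numpy(dtype=float)
    if len(pairs) < 2 or len(np.unique(bp)) < 2 or len(np.unique(cm)) < 2:
        return float("nan"), "ambiguous"
    tau, _ = kendalltau(bp, cm)
    if np.isnan(tau) or tau == 0:
        return float(tau), "ambiguous"
    return float(tau), ("forward" if tau > 0 else "reverse")


def anchor_scaffolds(map_frame: pd.DataFrame, scaffold_frame: pd.DataFrame):
    """Anchor scaffolds to linkage groups via shared mapped markers.

    Parameters
    ----------
    map_frame : columns group, marker, pos_cM.
    scaffold_frame : columns marker, scaffold, pos_bp (one row per marker).

    Returns
    -------
    anchors : list of ScaffoldAnchor (scaffold id order).
    summary : dict with scaffold counts, markers/scaffold mean, scaffolds
        per linkage group, unplaced-marker count and colocalization
        percentages under both denominators (scaffolds with >= 2 mapped
        markers, the default, and all scaffolds).
    """
    merged = map_frame.merge(scaffold_frame, on="marker", how="left")
    unplaced = merged[merged.scaffold.isna()]
    placed = merged.dropna(subset=["scaffold"])

    anchors: list[ScaffoldAnchor] = []
    for scaffold, sub in placed.groupby("scaffold", sort=True):
        counts = sub.group.value_counts()
        top = counts[counts == counts.max()]
        tied = len(top) > 1
        modal = None if tied else top.index[0]
        colocalized = (not tied) and (len(counts) == 1)
        pairs = sub[["marker", "pos_bp", "pos_cM", "group"]].reset_index(drop=True)
        if colocalized or (modal is not None):
            on_modal = pairs if colocalized else pairs[pairs.group == modal]
        else:
            on_modal = pairs.iloc[:0]
        tau, orientation = colinearity(on_modal)
        anchors.append(ScaffoldAnchor(
            scaffold=str(scaffold), group=modal, n_markers=len(sub),
            pairs=pairs, colocalized=colocalized, tau=tau,
            orientation=orientation))

    multi = [a for a in anchors if a.n_markers >= 2]
    coloc_multi = sum(a.colocalized for a in multi)
    coloc_all = sum(a.colocalized for a in anchors)
    groups_per_scaffolds: dict[str, set] = {}
    for a in anchors:
        if a.group is not None:
            groups_per_scaffolds.setdefault(a.group, set()).add(a.scaffold)
    summary = {
        "n_scaffolds": len(anchors),
        "n_mapped_markers_placed": int(len(placed)),
        "n_unplaced_markers": int(len(unplaced)),
        "mean_markers_per_scaffold": markers_per_scaffold(
            int(len(placed)), len(anchors)) if anchors else float("nan"),
        "scaffolds_per_group": {g: len(s) for g, s in
                                sorted(groups_per_scaffolds.items())},
        "mean_scaffolds_per_group": (
            float(np.mean([len(s) for s in groups_per_scaffolds.values()]))
            if groups_per_scaffolds else float("nan")),
        "n_scaffolds_multi_marker": len(multi),
        "colocalization_pct": (
            round(100.0 * coloc_multi / len(multi), 1) if multi else float("nan")),
        "colocalization_pct_incl_singletons": (
            round(100.0 * coloc_all / len(anchors), 1) if anchors else float("nan")),
    }
    return anchors, summary


def markers_per_scaffold(n_markers: int, n_scaffolds: int) -> float:
    """Mean mapped markers per scaffold, to two decimals."""
    return round(n_markers / n_scaffolds, 2)


def anchors_frame(anchors: list[ScaffoldAnchor]) -> pd.DataFrame:
    rows = [{
        "scaffold": a.scaffold,
        "group": a.group if a.group is not None else "ambiguous",
        "n_markers": a.n_markers,
        "tau": a.tau,
        "orientation": a.orientation,
        "colocalized": a.colocalized,
    } for a in anchors]
    return pd.DataFrame(
        rows, columns=["scaffold", "group", "n_markers", "tau", "orientation",
                       "colocalized"])


def figure_ready_anchors(anchors: list[ScaffoldAnchor], min_markers: int = 4):
    """Anchors dense enough to draw (>= 4 mapped markers)."""
    return [a for a in anchors if a.n_markers >= min_markers]


# ---------------------------------------------------------------------------
# Map comparison
# ---------------------------------------------------------------------------

_COMPARABLE = ("n_markers", "density_per_cM", "total_length_cM", "n_groups",
               "n_scaffolds", "n_links")


@dataclass
class MapComparison:
    new: dict
    old: dict
    ratios_pct: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"new": self.new, "old": self.old, "ratios_pct": self.ratios_pct}


def percent_ratio(new_value: float, old_value: float) -> int | None:
    """100 * new / old, rounded to integer percent; None for zero denominator."""
    if old_value == 0:
        return None
    return int(round(100.0 * new_value / old_value))


def compare_maps(metrics_new: dict, metrics_old: dict) -> MapComparison:
    """Integer-percent ratios between two maps' metrics.

    Only keys present in both metric dicts are compared; a zero denominator
    yields a flagged None ratio.
    """
    ratios = {}
    for key in _COMPARABLE:
        if key in metrics_new and key in metrics_old:
            ratios[key] = percent_ratio(metrics_new[key], metrics_old[key])
    return MapComparison(dict(metrics_new), dict(metrics_old), ratios)
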