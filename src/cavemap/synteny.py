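"""Cross-genome BLAST-hit resolution and synteny statistics.

Markers are anonymous 64-bp tags queried against a reference genome through
three routes — directly, via ~2-kb genomic flanks, and via transcript
sequences.  Raw 12-column tabular alignments are filtered by e-value
(default cutoff 10), collapsed to one hit per marker-target pairing (both
allele variants of a tag share the marker id), and multi-target markers are
resolved against per-linkage-group support sets built from single-hit
markers.  Resolution categories: ``single_robust``, ``top_supported``,
``top_unsupported``, ``not_top_supported``, ``unresolved`` (discarded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
_NUMERIC = {"pident": float, "length": int, "mismatch": int, "gapopen": int,
            "qstart": int, "qend": int, "sstart": int, "send": int,
            "evalue": float, "bitscore": float}

CATEGORIES = ("single_robust", "top_supported", "top_unsupported",
              "not_top_supported", "unresolved")

ROUTE_PRIORITY = {"genomic": 0, "transcriptomic": 1, "direct": 2}


@dataclass(frozen=True)
class ResolvedAssignment:
    marker_id: str
    target: str | None
    position: float | None          # bp midpoint of the retained alignment
    category: str
    route: str | None
    supporters: tuple[str, ...] = ()


def parse_hit_table(path, evalue_cutoff: float = 10.0, route: str | None = None) -> pd.DataFrame:
    """Parse a 12-column tabular alignment file, dropping rows above the
    e-value cutoff.  Malformed rows raise with the offending line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated fields, "
                    f"got {len(fields)}")
            record = dict(zip(HIT_COLUMNS, fields))
            try:
                for col, cast in _NUMERIC.items():
                    record[col] = cast(float(record[col])) if cast is int \
                        else cast(record[col])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            rows.append(record)
    frame = pd.DataFrame(rows, columns=HIT_COLUMNS)
    frame = frame[frame.evalue <= evalue_cutoff].reset_index(drop=True)
    if route is not None:
        frame["route"] = route
    return frame


def collapse_per_target(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep the single best hit per (marker, target) pairing.

    Best = lowest e-value; ties broken by higher identity, longer alignment,
    then lexicographic target position.  Both allele variants of a tag carry
    the same marker id, so this also collapses the allele pair.
    """
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        by=["qseqid", "sseqid", "evalue", "pident", "length", "sstart", "send"],
        ascending=[True, True, True, False, False, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(subset=["qseqid", "sseqid"],
                                   keep="first").reset_index(drop=True)


def build_support_sets(collapsed: pd.DataFrame, marker_group: dict[str, str]):
    """Per-linkage-group supported targets from single-robust markers.

    A marker with exactly one collapsed hit is a "single robust hit"; the
    support set of a group is the set of targets reported by that group's
    single-hit markers, together with the supporting marker ids.  Markers
    absent from the map contribute no support.
    """
    support: dict[str, dict[str, list[str]]] = {}
    counts = collapsed.groupby("qseqid").size()
    singles = counts[counts == 1].index
    single_hits = collapsed[collapsed.qseqid.isin(singles)]
    for _, row in single_hits.iterrows():
        group = marker_group.get(row.qseqid)
        if group is None:
            continue
        support.setdefault(group, {}).setdefault(row.sseqid, []).append(row.qseqid)
    return support


def _rank_key(row):
    return (row.evalue, -row.pident, -row.length, row.sstart, row.send)


def resolve_marker(marker_hits: pd.DataFrame,
                   support: dict[str, list[str]] | None) -> ResolvedAssignment:
    """Resolve one marker's collapsed hits against its group's support set.

    Exactly one hit -> ``single_robust``.  Otherwise the top hit has the
    lowest e-value (ties broken by highest identity); a supported top hit is
    retained as ``top_supported``; if only another hit's target is supported,
    that hit is retained as ``not_top_supported`` (lowest e-value among the
    supported ones); with no support anywhere the top hit is kept as
    ``top_unsupported``; if the top cannot be determined (e-value and
    identity tied across different targets) and nothing is supported, the
    marker is ``unresolved`` and discarded.
    """
    if marker_hits.empty:
        raise ValueError("resolve_marker requires at least one hit")
    support = support or {}
    mid = marker_hits.qseqid.iloc[0]
    hits = list(marker_hits.itertuples(index=False))

    def assignment(row, category):
        supporters = tuple(sorted(support.get(row.sseqid, ())))
        mid_bp = (row.sstart + row.send) / 2.0
        return ResolvedAssignment(mid, row.sseqid, mid_bp, category,
                                  getattr(row, "route", None), supporters)

    if len(hits) == 1:
        return assignment(hits[0], "single_robust")

    hits.sort(key=_rank_key)
    top = hits[0]
    top_tied = [h for h in hits
                if h.evalue == top.evalue and h.pident == top.pident]
    ambiguous_top = len({h.sseqid for h in top_tied}) > 1

    supported = [h for h in hits if h.sseqid in support]
    if ambiguous_top:
        tied_supported = [h for h in top_tied if h.sseqid in support]
        if tied_supported:
            return assignment(min(tied_supported, key=_rank_key), "top_supported")
        if supported:
            return assignment(min(supported, key=_rank_key), "not_top_supported")
        return ResolvedAssignment(mid, None, None, "unresolved", None, ())
    if top.sseqid in support:
        return assignment(top, "top_supported")
    if supported:
        return assignment(min(supported, key=_rank_key), "not_top_supported")
    return assignment(top, "top_unsupported")


def resolve_route(collapsed: pd.DataFrame, marker_group: dict[str, str]):
    """Two-pass resolution of one route's collapsed hit table.

    First pass builds per-group support sets from single-hit markers; second
    pass resolves every marker with >= 1 hit.  Returns a dict marker ->
    ResolvedAssignment.
    """
    support_sets = build_support_sets(collapsed, marker_group)
    out: dict[str, ResolvedAssignment] = {}
    for mid, sub in collapsed.groupby("qseqid", sort=True):
        group = marker_group.get(mid)
        support = support_sets.get(group) if group is not None else None
        out[mid] = resolve_marker(sub, support)
    return out


def combine_routes(route_results: dict[str, dict[str, ResolvedAssignment]],
                   route_tables: dict[str, pd.DataFrame],
                   marker_group: dict[str, str]):
    """Combine per-route retained hits into one assignment per marker.

    Each route's retained hit (the resolved alignment, not the discarded
    alternatives) enters a candidate set which is re-resolved with the same
    filtering process; candidate ties across routes break by route priority
    genomic > transcriptomic > direct.  Support sets are rebuilt from markers
    whose combined candidate set names a single target.
    """
    candidates: dict[str, list] = {}
    for route, table in route_tables.items():
        resolved = route_results[route]
        for mid, assignment in resolved.items():
            if assignment.target is None:
                continue
            sub = table[(table.qseqid == mid) & (table.sseqid == assignment.target)]
            row = sub.iloc[0].copy()
            row["route"] = route
            candidates.setdefault(mid, []).append(row)

    frames = {mid: pd.DataFrame(rows) for mid, rows in candidates.items()}

    # support from markers whose candidate targets agree on one target
    support_sets: dict[str, dict[str, list[str]]] = {}
    for mid, frame in frames.items():
        group = marker_group.get(mid)
        if group is None:
            continue
        targets = set(frame.sseqid)
        if len(targets) == 1:
            support_sets.setdefault(group, {}).setdefault(
                targets.pop(), []).append(mid)

    out: dict[str, ResolvedAssignment] = {}
    for mid, frame in frames.items():
        frame = frame.assign(
            _prio=[ROUTE_PRIORITY.get(r, 99) for r in frame.route])
        frame = frame.sort_values(
            by=["evalue", "pident", "length", "_prio"],
            ascending=[True, False, False, True], kind="mergesort",
        ).drop(columns="_prio")
        # a marker may present the same target through several routes;
        # keep the best alignment per target before resolving
        frame = frame.drop_duplicates(subset="sseqid", keep="first")
        group = marker_group.get(mid)
        support = support_sets.get(group) if group is not None else None
        out[mid] = resolve_marker(frame, support)
    return out


def extract_flank(scaffold_length: int, marker_bp: int, width: int = 2000,
                  tag_length: int = 64) -> tuple[int, int]:
    """1-based inclusive ~``width``-bp interval centered on the 64-bp tag.

    Clipped at scaffold ends while preserving the width where possible; the
    returned interval always contains the tag.
    """
    if marker_bp < 1 or marker_bp + tag_length - 1 > scaffold_length:
        raise ValueError(
            f"tag at {marker_bp} (+{tag_length} bp) outside scaffold of "
            f"length {scaffold_length}")
    width = min(width, scaffold_length)
    pad = (width - tag_length) // 2
    start = marker_bp - pad
    end = start + width - 1
    if start < 1:
        start, end = 1, width
    if end > scaffold_length:
        end = scaffold_length
        start = end - width + 1
    return start, end


# ---------------------------------------------------------------------------
# Synteny links and statistics
# ---------------------------------------------------------------------------


def links_frame(assignments: dict[str, ResolvedAssignment],
                map_frame: pd.DataFrame) -> pd.DataFrame:
    """One synteny link per resolved mapped marker.

    ``map_frame``: columns group, marker, pos_cM.  Output columns: marker,
    group, pos_cM, target, target_bp, category, route.
    """
    placed = map_frame.set_index("marker")
    rows = []
    for mid, a in sorted(assignments.items()):
        if a.target is None or mid not in placed.index:
            continue
        rows.append({"marker": mid, "group": placed.at[mid, "group"],
                     "pos_cM": placed.at[mid, "pos_cM"], "target": a.target,
                     "target_bp": a.position, "category": a.category,
                     "route": a.route})
    return pd.DataFrame(
        rows, columns=["marker", "group", "pos_cM", "target", "target_bp",
                       "category", "route"])


def category_counts(assignments: dict[str, ResolvedAssignment],
                    n_queries: int) -> pd.DataFrame:
    """Table-style resolution-category counts and rates for one route."""
    counts = {c: 0 for c in CATEGORIES}
    for a in assignments.values():
        counts[a.category] += 1
    counts["no_result"] = n_queries - len(assignments)
    rows = [{"category": c, "n": n,
             "percent": round(100.0 * n / n_queries, 1) if n_queries else 0.0}
            for c, n in counts.items()]
    return pd.DataFrame(rows).set_index("category")


def resolution_rate(n_identified: int, n_queries: int) -> float:
    """Percent of queried markers with a retained cross-genome location."""
    return round(100.0 * n_identified / n_queries, 1)


def mean_links_per_chromosome(link_counts) -> float:
    """Mean per-chromosome syntenic-link count, to two decimals."""
    return round(float(np.mean(np.asarray(link_counts, dtype=float))), 2)


def oxford_matrix(links: pd.DataFrame) -> pd.DataFrame:
    """Linkage-group x target-chromosome link-count matrix."""
    if links.empty:
        return pd.DataFrame()
    return links.pivot_table(index="group", columns="target", values="marker",
                             aggfunc="count", fill_value=0)


def circos_lines(links: pd.DataFrame, span_cM: float = 0.5,
                 span_bp: int = 500_000) -> list[str]:
    """Circos-format link lines: ``group start end chrom start end``."""
    lines = []
    for _, row in links.iterrows():
        lines.append(
            f"{row.group} {row.pos_cM:.3f} {row.pos_cM + span_cM:.3f} "
            f"{row.target} {int(row.target_bp)} {int(row.target_bp) + span_bp}")
    return lines


def synteny_stats(links: pd.DataFrame, chrom_lengths_mb: dict[str, float],
                  strong_group_links: int = 10,
                  represented_min_links: int = 5) -> dict:
    """Per-chromosome synteny report.

    For each target chromosome: link count, represented linkage groups (those
    with >= ``represented_min_links`` links flagged as strongly represented),
    and links/Mb.  Chromosomes are then compared between those with and
    without a >= ``strong_group_links``-link concentration on a single group
    (pooled-variance two-sample t test on links/Mb).
    """
    if links.empty:
        return {"per_chromosome": [], "mean_links_per_chromosome": 0.0,
                "mean_links_per_mb": float("nan"), "t_test": None,
                "total_links": 0}
    per_chrom = []
    matrix = oxford_matrix(links)
    for chrom, sub in links.groupby("target"):
        group_counts = matrix[chrom] if chrom in matrix.columns else pd.Series(dtype=int)
        groups = sorted(group_counts[group_counts > 0].index)
        flagged = sorted(group_counts[group_counts >= represented_min_links].index)
        length = chrom_lengths_mb.get(chrom)
        entry = {
            "chromosome": chrom,
            "n_links": int(len(sub)),
            "groups": groups,
            "strongly_represented_groups": flagged,
            "max_single_group_links": int(group_counts.max()) if len(group_counts) else 0,
        }
        if length is None:
            entry["links_per_mb"] = None
        else:
            entry["links_per_mb"] = len(sub) / length
        per_chrom.append(entry)

    with_len = [e for e in per_chrom if e["links_per_mb"] is not None]
    strong = [e["links_per_mb"] for e in with_len
              if e["max_single_group_links"] >= strong_group_links]
    weak = [e["links_per_mb"] for e in with_len
            if e["max_single_group_links"] < strong_group_links]
    t_test = None
    if len(strong) >= 2 and len(weak) >= 2:
        t, p = stats.ttest_ind(strong, weak, equal_var=True)
        t_test = {"t": float(t), "p": float(p),
                  "df": len(strong) + len(weak) - 2,
                  "mean_strong": float(np.mean(strong)), "n_strong": len(strong),
                  "mean_weak": float(np.mean(weak)), "n_weak": len(weak)}
    return {
        "per_chromosome": per_chrom,
        "total_links": int(len(links)),
        "mean_links_per_chromosome": mean_links_per_chromosome(
            [e["n_links"] for e in per_chrom]),
        "mean_links_per_mb": (
            float(np.mean([e["links_per_mb"] for e in with_len]))
            if with_len else float("nan")),
        "t_test": t_test,
    }
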