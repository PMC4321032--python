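"""Marker screening and cross-type coding for the F2 panel design.

Rules implemented, in order: (1) parental consensus assignment from the
four-individual founder panels (>= 3-of-4 identical nucleotides; heterozygote
codes never form a parental consensus), with F1 heterozygote confirmation as
an advisory flag; (2) discard when neither parental genotype can be assigned
or the assigned genotypes are identical; (3) discard uninformative markers (a
single genotype class across all F2 individuals); (4) discard markers whose
1:2:1 segregation chi-square exceeds the cutoff (default 50).  Surviving
markers are coded ``a`` (homozygous surface), ``h`` (heterozygous), ``b``
(homozygous cave) per F2 individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cavemap.iupac import (
    HET_TO_PAIR,
    MISSING,
    het_code,
    is_het,
    is_nucleotide,
)
from cavemap.simcross import MarkerPanelSet

CODE_MISSING = "-"

STATUS_RETAINED = "retained"
STATUS_NO_PARENT = "discarded_no_parent"
STATUS_IDENTICAL = "discarded_identical_parents"
STATUS_UNINFORMATIVE = "discarded_uninformative"
STATUS_DISTORTED = "discarded_distorted"


@dataclass
class CodedMarker:
    marker_id: str
    surface_allele: str | None
    cave_allele: str | None
    f2_codes: np.ndarray            # '<U1' over {'a','h','b','-'}
    chi2: float | None
    status: str
    f1_flag: bool = False           # F1 consensus missing/inconsistent (advisory)
    n_inconsistent: int = 0         # F2 calls matching neither assigned allele


@dataclass
class QcReport:
    """Telescoping filter-stage bookkeeping.

    Every stage count equals the previous stage minus that stage's removals:
    ``suitable = total - no_parent - identical_parents``,
    ``screened = suitable - uninformative``,
    ``retained = screened - distorted``.
    """

    total: int = 0
    no_parent: int = 0
    identical_parents: int = 0
    uninformative: int = 0
    distorted: int = 0
    f1_flagged: int = 0
    inconsistent_calls: int = 0

    @property
    def suitable(self) -> int:
        return self.total - self.no_parent - self.identical_parents

    @property
    def screened(self) -> int:
        return self.suitable - self.uninformative

    @property
    def retained(self) -> int:
        return self.screened - self.distorted

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "no_parent": self.no_parent,
            "identical_parents": self.identical_parents,
            "suitable": self.suitable,
            "uninformative": self.uninformative,
            "screened": self.screened,
            "distorted": self.distorted,
            "retained": self.retained,
            "f1_flagged": self.f1_flagged,
            "inconsistent_calls": self.inconsistent_calls,
        }


def _consensus_threshold(panel_size: int) -> int:
    # 3-of-4 at the default panel size; ceil(3n/4) otherwise (non-default)
    return math.ceil(3 * panel_size / 4)


def assign_parental_consensus(calls, panel_size: int = 4) -> str | None:
    """Consensus nucleotide of one founder panel, or None (``NA``).

    A nucleotide present in >= 3 of the 4 calls wins (missing calls and
    heterozygote codes count as non-matching and never form a consensus).
    """
    calls = list(calls)
    if len(calls) != panel_size:
        raise ValueError(f"expected {panel_size} calls, got {len(calls)}")
    need = _consensus_threshold(panel_size)
    counts: dict[str, int] = {}
    for call in calls:
        if is_nucleotide(call):
            counts[call] = counts.get(call, 0) + 1
    winners = [nt for nt, c in counts.items() if c >= need]
    return winners[0] if len(winners) == 1 else None


def assign_f1_heterozygote(calls, panel_size: int = 4) -> str | None:
    """Shared heterozygote code of >= 3-of-4 F1 calls, or None."""
    calls = list(calls)
    if len(calls) != panel_size:
        raise ValueError(f"expected {panel_size} calls, got {len(calls)}")
    need = _consensus_threshold(panel_size)
    counts: dict[str, int] = {}
    for call in calls:
        if is_het(call):
            counts[call] = counts.get(call, 0) + 1
    winners = [code for code, c in counts.items() if c >= need]
    return winners[0] if len(winners) == 1 else None


def chisq_segregation(n_a: int, n_h: int, n_b: int) -> float:
    """Pearson chi-square of (n_a, n_h, n_b) against the 1:2:1 F2 expectation.

    Missing calls are excluded before counting; n = n_a + n_h + n_b must be
    >= 1.
    """
    if min(n_a, n_h, n_b) < 0:
        raise ValueError("counts must be nonnegative")
    n = n_a + n_h + n_b
    if n == 0:
        raise ValueError("no informative F2 calls")
    expected = np.array([n / 4.0, n / 2.0, n / 4.0])
    observed = np.array([n_a, n_h, n_b], dtype=float)
    return float(((observed - expected) ** 2 / expected).sum())


def _code_f2(calls: np.ndarray, surface: str, cave: str):
    het = het_code(surface, cave)
    codes = np.full(calls.shape, CODE_MISSING, dtype="<U1")
    codes[calls == surface] = "a"
    codes[calls == het] = "h"
    codes[calls == cave] = "b"
    inconsistent = int(((calls != MISSING) & (codes == CODE_MISSING)).sum())
    return codes, inconsistent


def _complete_allele_pair(surface, cave, f1_code):
    """Infer a single missing parental allele from the F1 heterozygote code.

    With one consensus missing, the marker is only usable if the F1
    heterozygote code pins down the allele pair and one member matches the
    assigned parent; otherwise the pair cannot be completed.
    """
    if f1_code is None:
        return surface, cave
    pair = set(HET_TO_PAIR[f1_code])
    if surface is None and cave in pair and len(pair) == 2:
        return (pair - {cave}).pop(), cave
    if cave is None and surface in pair and len(pair) == 2:
        return surface, (pair - {surface}).pop()
    return surface, cave


def screen_and_code(panelset: MarkerPanelSet, chi2_cutoff: float = 50.0,
                    panel_size: int = 4, require_f1: bool = False):
    """Screen and code every marker; return ``(coded_markers, report)``.

    Statuses are assigned in screening order: parental-assignment discards
    first, then uninformative markers, then the segregation-distortion
    chi-square filter.  F2 calls inconsistent with either assigned allele are
    coded missing and counted.  F1 confirmation is advisory (flag only)
    unless ``require_f1`` is set.
    """
    report = QcReport(total=len(panelset.marker_ids))
    coded: list[CodedMarker] = []
    n_f2 = panelset.f2.shape[1]

    surface_calls = panelset.surface.to_numpy()
    cave_calls = panelset.cave.to_numpy()
    f1_calls = panelset.f1.to_numpy()
    f2_calls = panelset.f2.to_numpy()

    for k, mid in enumerate(panelset.marker_ids):
        surface = assign_parental_consensus(surface_calls[k], panel_size)
        cave = assign_parental_consensus(cave_calls[k], panel_size)
        f1 = assign_f1_heterozygote(f1_calls[k], panel_size)

        if surface is None or cave is None:
            surface, cave = _complete_allele_pair(surface, cave, f1)

        empty = np.full(n_f2, CODE_MISSING, dtype="<U1")
        if surface is None or cave is None:
            report.no_parent += 1
            coded.append(CodedMarker(mid, surface, cave, empty, None,
                                     STATUS_NO_PARENT))
            continue
        if surface == cave:
            report.identical_parents += 1
            coded.append(CodedMarker(mid, surface, cave, empty, None,
                                     STATUS_IDENTICAL))
            continue

        f1_flag = f1 != het_code(surface, cave)
        if f1_flag:
            report.f1_flagged += 1
        if require_f1 and f1_flag:
            report.no_parent += 1
            coded.append(CodedMarker(mid, surface, cave, empty, None,
                                     STATUS_NO_PARENT, f1_flag=True))
            continue

        codes, inconsistent = _code_f2(f2_calls[k], surface, cave)
        report.inconsistent_calls += inconsistent
        counts = {c: int((codes == c).sum()) for c in "ahb"}
        observed_classes = sum(1 for c in "ahb" if counts[c] > 0)
        if observed_classes <= 1:
            report.uninformative += 1
            coded.append(CodedMarker(mid, surface, cave, codes, None,
                                     STATUS_UNINFORMATIVE, f1_flag=f1_flag,
                                     n_inconsistent=inconsistent))
            continue

        chi2 = chisq_segregation(counts["a"], counts["h"], counts["b"])
        if chi2 > chi2_cutoff:
            report.distorted += 1
            status = STATUS_DISTORTED
        else:
            status = STATUS_RETAINED
        coded.append(CodedMarker(mid, surface, cave, codes, chi2, status,
                                 f1_flag=f1_flag, n_inconsistent=inconsistent))
    return coded, report


def retained(coded: list[CodedMarker]) -> list[CodedMarker]:
    return [m for m in coded if m.status == STATUS_RETAINED]


def codes_matrix(coded: list[CodedMarker]):
    """Integer code matrix (m, n) for a coded-marker list: a/h/b -> 0/1/2, -1 missing."""
    lut = {"a": 0, "h": 1, "b": 2, CODE_MISSING: -1}
    ids = [m.marker_id for m in coded]
    mat = np.array([[lut[c] for c in m.f2_codes] for m in coded], dtype=np.int8)
    return ids, mat


def coded_frame(coded: list[CodedMarker], individuals=None) -> pd.DataFrame:
    """Coded markers as a DataFrame (metadata columns then per-individual codes)."""
    n_f2 = len(coded[0].f2_codes) if coded else 0
    if individuals is None:
        individuals = [f"F2_{i + 1:03d}" for i in range(n_f2)]
    rows = []
    for m in coded:
        row = {
            "marker": m.marker_id,
            "surface_allele": m.surface_allele or MISSING,
            "cave_allele": m.cave_allele or MISSING,
            "chi2": m.chi2 if m.chi2 is not None else float("nan"),
            "status": m.status,
        }
        row.update(dict(zip(individuals, m.f2_codes)))
        rows.append(row)
    return pd.DataFrame(rows).set_index("marker")
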