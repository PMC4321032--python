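"""File formats: tab-separated tables with '#'-prefixed headers, FASTA, JSON.

Missing values are spelled ``NA`` in genotype files (matching the raw-call
vocabulary) and ``-`` in coded files.  Readers validate strictly and raise
with the offending row/column; writers and readers round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from cavemap.iupac import CALL_ALPHABET, MISSING
from cavemap.linkage import GeneticMap, LinkageGroup
from cavemap.marker_qc import CODE_MISSING
from cavemap.simcross import MarkerPanelSet

_CODED_META = ["surface_allele", "cave_allele", "chi2", "status"]


def _write_tsv(frame: pd.DataFrame, path, float_format=None):
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#" + "\t".join(map(str, frame.columns)) + "\n")
        frame.to_csv(fh, sep="\t", header=False, index=False,
                     float_format=float_format)


def _read_tsv(path, dtype=None) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected '#'-prefixed header line")
        columns = header[1:].split("\t")
        frame = pd.read_csv(fh, sep="\t", header=None, names=columns,
                            dtype=dtype, na_filter=False)
    return frame


# -- genotype matrix ---------------------------------------------------------


def write_genotypes(panelset: MarkerPanelSet, path):
    """Genotype TSV: rows = markers; columns = panel individuals (S*, C*,
    F1_*, F2_*)."""
    frame = pd.concat([panelset.surface, panelset.cave, panelset.f1,
                       panelset.f2], axis=1)
    frame = frame.reset_index(names="marker")
    _write_tsv(frame, path)


def read_genotypes(path) -> MarkerPanelSet:
    frame = _read_tsv(path, dtype=str)
    if frame.columns[0] != "marker":
        raise ValueError(f"{path}: first column must be 'marker'")
    frame = frame.set_index("marker")
    frame.index.name = None
    for row, (mid, calls) in enumerate(frame.iterrows(), start=2):
        bad = [c for c, v in calls.items() if v not in CALL_ALPHABET]
        if bad:
            raise ValueError(
                f"{path}: row {row} (marker {mid}), column {bad[0]}: illegal "
                f"genotype symbol {calls[bad[0]]!r}")
    def cols(prefix):
        return [c for c in frame.columns if c.startswith(prefix)]
    surface = frame[[c for c in frame.columns
                     if c.startswith("S") and not c.startswith("S_")]]
    cave = frame[cols("C")]
    f1 = frame[cols("F1_")]
    f2 = frame[cols("F2_")]
    if not (len(surface.columns) and len(cave.columns)
            and len(f1.columns) and len(f2.columns)):
        raise ValueError(f"{path}: missing panel columns (S*/C*/F1_*/F2_*)")
    tags = pd.DataFrame(index=frame.index,
                        columns=["tag_surface", "tag_cave"], dtype=str)
    return MarkerPanelSet(list(frame.index), tags, surface, cave, f1, f2)


# -- coded markers -----------------------------------------------------------


def write_coded(coded_frame: pd.DataFrame, path):
    frame = coded_frame.reset_index()
    frame["chi2"] = [("NA" if pd.isna(v) else repr(float(v)))
                     for v in frame["chi2"]]
    _write_tsv(frame, path)


def read_coded(path) -> pd.DataFrame:
    frame = _read_tsv(path, dtype=str).set_index("marker")
    frame["chi2"] = [float("nan") if v == "NA" else float(v)
                     for v in frame["chi2"]]
    code_cols = [c for c in frame.columns if c not in _CODED_META]
    allowed = {"a", "h", "b", CODE_MISSING}
    for row, (mid, values) in enumerate(frame[code_cols].iterrows(), start=2):
        bad = [c for c, v in values.items() if v not in allowed]
        if bad:
            raise ValueError(
                f"{path}: row {row} (marker {mid}), column {bad[0]}: illegal "
                f"code {values[bad[0]]!r}")
    return frame


def coded_codes_matrix(coded_frame: pd.DataFrame, retained_only=True):
    """(marker_ids, int8 matrix, individuals) from a coded-marker frame."""
    frame = coded_frame
    if retained_only:
        frame = frame[frame.status == "retained"]
    code_cols = [c for c in frame.columns if c not in _CODED_META]
    lut = {"a": 0, "h": 1, "b": 2, CODE_MISSING: -1}
    mat = frame[code_cols].apply(lambda col: col.map(lut)).to_numpy(dtype=np.int8)
    return list(frame.index), mat, code_cols


# -- map ---------------------------------------------------------------------


def map_frame(genetic_map: GeneticMap) -> pd.DataFrame:
    rows = [
        {"group": g.group_id, "marker": m, "pos_cM": p}
        for g in genetic_map.groups
        for m, p in zip(g.markers, g.positions)
    ]
    return pd.DataFrame(rows, columns=["group", "marker", "pos_cM"])


def write_map(genetic_map: GeneticMap, path):
    frame = map_frame(genetic_map)
    frame["pos_cM"] = [repr(round(p, 6)) for p in frame.pos_cM]
    _write_tsv(frame, path)


def read_map(path) -> pd.DataFrame:
    frame = _read_tsv(path, dtype={"group": str, "marker": str,
                                   "pos_cM": float})
    missing = {"group", "marker", "pos_cM"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing map columns {sorted(missing)}")
    return frame


def map_from_frame(frame: pd.DataFrame) -> GeneticMap:
    groups = []
    for gid, sub in frame.groupby("group", sort=True):
        sub = sub.sort_values("pos_cM", kind="mergesort")
        pos = sub.pos_cM.to_numpy(dtype=float)
        groups.append(LinkageGroup(str(gid), list(sub.marker), pos - pos[0]))
    groups.sort(key=lambda g: (-g.n_markers, g.group_id))
    return GeneticMap(groups)


# -- simple two/three-column tables -----------------------------------------


def write_phenotypes(phenotypes: pd.Series, path):
    frame = pd.DataFrame({"individual": phenotypes.index,
                          "phenotype": phenotypes.to_numpy().astype(int)})
    _write_tsv(frame, path)


def read_phenotypes(path) -> pd.Series:
    frame = _read_tsv(path, dtype={"individual": str, "phenotype": int})
    bad = ~frame.phenotype.isin((0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}: row {row}: phenotype must be 0 or 1")
    return pd.Series(frame.phenotype.to_numpy(), index=frame.individual,
                     name="phenotype")


def write_scaffold_table(truth_markers: pd.DataFrame, path):
    """Marker -> scaffold TSV (marker, scaffold, 1-based bp position)."""
    frame = truth_markers.reset_index()[["marker", "scaffold", "scaffold_bp"]]
    frame = frame.rename(columns={"scaffold_bp": "pos_bp"})
    _write_tsv(frame, path)


def read_scaffold_table(path) -> pd.DataFrame:
    frame = _read_tsv(path, dtype={"marker": str, "scaffold": str,
                                   "pos_bp": int})
    missing = {"marker", "scaffold", "pos_bp"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def write_chrom_lengths(lengths_mb: dict[str, float], path):
    frame = pd.DataFrame({"chromosome": list(lengths_mb),
                          "length_mb": [lengths_mb[c] for c in lengths_mb]})
    _write_tsv(frame, path)


def read_chrom_lengths(path) -> dict[str, float]:
    frame = _read_tsv(path, dtype={"chromosome": str, "length_mb": float})
    return dict(zip(frame.chromosome, frame.length_mb))


# -- alignment tables (12-column tabular, headerless) ------------------------


def write_hit_table(hits: pd.DataFrame, path):
    from cavemap.synteny import HIT_COLUMNS

    hits[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# -- FASTA -------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path, wrap: int = 60):
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- misc --------------------------------------------------------------------


def write_circos_links(lines: list[str], path):
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
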