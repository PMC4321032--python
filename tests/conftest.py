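import pandas as pd
import pytest

from cavemap.linkage import build_map
from cavemap.marker_qc import codes_matrix, retained, screen_and_code
from cavemap.simcross import SimConfig, simulate_cross


@pytest.fixture(scope="session")
def small_cross():
    """3 chromosomes x 20 markers, 60 cM each, recessive trait at 30 cM of
    chromosome 1 (a typed marker position)."""
    config = SimConfig(n_chromosomes=3, markers_per_chromosome=20,
                       chrom_length_cM=60.0, trait_locus=(1, 30.0), seed=3)
    truemap, panelset, phenotypes = simulate_cross(config)
    return config, truemap, panelset, phenotypes


@pytest.fixture(scope="session")
def small_coded(small_cross):
    _, _, panelset, _ = small_cross
    coded, report = screen_and_code(panelset)
    return coded, report


@pytest.fixture(scope="session")
def small_map(small_cross, small_coded):
    coded, _ = small_coded
    ids, codes = codes_matrix(retained(coded))
    gmap, audit = build_map(ids, codes)
    return gmap, audit, ids, codes


@pytest.fixture(scope="session")
def small_codes_frame(small_cross, small_map):
    _, _, panelset, _ = small_cross
    _, _, ids, codes = small_map
    return pd.DataFrame(codes, index=ids, columns=panelset.f2.columns)


def true_genetic_map(truemap):
    """Build a GeneticMap directly from simulation ground truth."""
    from cavemap.linkage import GeneticMap, LinkageGroup

    groups = []
    for chrom, ids in truemap.chromosomes.items():
        pos = truemap.markers.loc[ids, "pos_cM"].to_numpy(dtype=float)
        groups.append(LinkageGroup(f"chr{chrom}", list(ids), pos - pos[0]))
    return GeneticMap(groups)
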