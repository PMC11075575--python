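"""Packaged reference data: the published two-species count table, the
default family/subfamily taxonomy, and the default diplogastrid species tree.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

#: Ladder phylogeny of the eight Pristionchus species used throughout the
#: gene-loss analyses (sister pair P. pacificus + P. exspectatus at the tip).
DEFAULT_SPECIES_TREE = (
    "(((((((P_pacificus,P_exspectatus),P_arcanus),P_maxplancki),"
    "P_japonicus),P_mayeri),P_entomophagus),P_fissidentatus);"
)

FAMILIES = [
    "HAT", "HDAC", "HMT", "HDMT", "HISTONE", "DNA_METH", "NCRNA",
    "REMODELER", "OTHER",
]


def _data(name: str):
    return resources.files("epitoolkit.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """Two-species epigenetic gene counts per family/subfamily.

    Columns: family, subfamily, P_pacificus, C_elegans. Grand totals are 291
    (P. pacificus) and 265 (C. elegans).
    """
    with resources.as_file(_data("table1_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_default_taxonomy() -> dict:
    """Default domain->family/subfamily taxonomy (see data/taxonomy.yaml).

    Returns a dict with keys ``domain_map`` (accession -> {family, subfamily})
    and ``reference_map`` (protein id -> {family, subfamily}).
    """
    with resources.as_file(_data("taxonomy.yaml")) as p:
        return yaml.safe_load(p.read_text())
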