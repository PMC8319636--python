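"""Packaged reference tables.

``key_protein_centrality`` is the worked-example centrality table for the
eleven key proteins of the Alzheimer's-disease neuroinflammation
interaction network (IL10, TLR4, IL6, AKT1, CRP, IL4, CXCL8, TNF, ITGAM,
CCL2, NOS3) with their published degree and betweenness values, stored
with decimal points. The network they come from was built from a
high-confidence (score >= 0.7) interaction export whose 52-protein
universe had mean degree 9.38 and mean betweenness 47.69; only the eleven
rows passing both means are available, so the fixture is the selection's
worked example, not a recomputation input.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .network import CentralityRecord, read_centrality_table

#: Published selection thresholds of the worked example (mean degree,
#: mean betweenness over the full 52-protein universe).
KEY_PROTEIN_THRESHOLDS = (9.38, 47.69)
KEY_PROTEIN_UNIVERSE_SIZE = 52
KEY_PROTEIN_EDGE_COUNT = 244


def key_protein_centrality_path() -> Path:
    return Path(str(files("keynet.data") / "key_protein_centrality.tsv"))


def load_key_protein_centrality() -> list[CentralityRecord]:
    """The 11-row worked-example centrality table, betweenness-descending."""
    return read_centrality_table(key_protein_centrality_path())
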