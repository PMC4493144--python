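"""Packaged reference data.

Two small fixtures ship with the package:

* the published hierarchical character key for Mediterranean scombrid COI
  barcodes (612-column frame, genus-first), including the *Auxis* compound
  triple and the five-species *Thunnus* residual group, and
* the published three-site larval composition survey (n = 188 larvae).
"""

from __future__ import annotations

from importlib import resources as _res

import pandas as pd

from .ca_key import IdentificationKey, key_from_dict
from .pipeline import CompositionTable

_KEY_FILE = "mediterranean_scombrids_key.json"
_COMPOSITION_FILE = "mediterranean_larvae_composition.tsv"


def load_mediterranean_key() -> IdentificationKey:
    """The published Mediterranean-scombrid character key (612-column frame)."""
    import json

    with _res.files("scombkey.data").joinpath(_KEY_FILE).open() as fh:
        return key_from_dict(json.load(fh))


def load_survey_composition() -> CompositionTable:
    """The published larval composition counts by sampling site."""
    with _res.files("scombkey.data").joinpath(_COMPOSITION_FILE).open() as fh:
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    return CompositionTable(frame)
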