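"""Allotype reference table.

The pipeline identifies allotypes by matching deconvoluted intact masses
against a reference of Fc/2 backbone average masses.  A table ships with
the package (``data/allotypes_synthetic.tsv``): it lists IMGT-style
allotype names with *synthetic but realistic* backbone masses in the
23.7-24.3 kDa Fc/2 range, because no sequence set is bundled.  Replace it
with your own TSV (same columns) to analyse real data.

When a backbone amino-acid sequence is available, :func:`backbone_mass_from_sequence`
computes the average mass assuming the two intrachain disulfides
(C_H2 and C_H3) are closed.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Union

import pandas as pd
from pyteomics import mass as _pmass

from .proteoforms import Allotype

__all__ = [
    "load_allotype_reference",
    "allotypes_by_name",
    "backbone_mass_from_sequence",
]

_COLUMNS = ["name", "subclass", "backbone_mass_avg", "n_glyc_sites", "openSS_truncation_delta"]


def load_allotype_reference(path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """Load an allotype reference TSV.

    Columns: ``name, subclass, backbone_mass_avg, n_glyc_sites,
    openSS_truncation_delta``.  With no path, the synthetic table bundled
    with the package is returned.
    """
    if path is None:
        with resources.files("fcprofiler.data").joinpath("allotypes_synthetic.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allotype reference is missing columns: {missing}")
    if (table.groupby("subclass")["name"].count() > 2).any():
        # a diploid patient carries at most two allotypes per subclass, but
        # the reference may list more candidates; only warn via validation
        # at calling time.  Here we only check basic sanity.
        pass
    if (table["backbone_mass_avg"] <= 0).any():
        raise ValueError("backbone_mass_avg must be positive")
    return table


def allotypes_by_name(table: pd.DataFrame) -> Dict[str, Allotype]:
    """Convert a reference table into :class:`Allotype` objects keyed by name."""
    out: Dict[str, Allotype] = {}
    for row in table.itertuples(index=False):
        out[row.name] = Allotype(
            name=row.name,
            subclass=row.subclass,
            backbone_mass_avg=float(row.backbone_mass_avg),
            n_glyc_sites=int(row.n_glyc_sites),
            openss_truncation_delta=float(row.openSS_truncation_delta),
        )
    return out


def backbone_mass_from_sequence(sequence: str, n_closed_disulfides: int = 2) -> float:
    """Average mass of an unglycosylated Fc/2 backbone from its sequence.

    Each closed disulfide bridge removes two hydrogens (-2.016 Da).
    """
    m = _pmass.calculate_mass(sequence=sequence, average=True)
    return m - n_closed_disulfides * 2.0159
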