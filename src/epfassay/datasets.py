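"""Bundled reference datasets.

Published summary tables from a screening study of 27 wild *Beauveria
bassiana* isolates baited from Ethiopian cropland, grassland and forest
soils: per-isolate spore germination (SG), first plate-sporulation day
(DPCS) with its relative sporulation rate (RSR), wax-moth larval mortality
(LM) and the resulting Biological Efficacy Index; leafminer pathogenicity
of the 12 screened isolates on second and third instar larvae with cadaver
spore yields; and ordinal enzyme clear-zone grades of the five most
virulent isolates. The SG/RSR/LM columns are inputs to the screening
module; the printed BEI column serves as an independent check of the index
computation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("epfassay.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_screening_reference() -> pd.DataFrame:
    """27-isolate screening table (SG, DPCS, RSR, LM, published BEI, selection)."""
    return _load("reference_screening.csv")


def load_pathogenicity_reference() -> pd.DataFrame:
    """12-isolate leafminer pathogenicity table (both instars, cadaver yields)."""
    return _load("reference_pathogenicity.csv")


def load_enzyme_reference() -> pd.DataFrame:
    """Clear-zone enzyme grades (-, +, ++, +++) of the five most virulent isolates."""
    return _load("reference_enzymes.csv")
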