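"""Packaged reference datasets.

The only dataset that ships with the package is the published scat
composition table for the two sympatric civets of Pir Lasura National Park
(Asian palm civet, n = 108 scats; small Indian civet, n = 44 scats):
frequency of occurrence of 33 food-item categories, grouped as wild animal,
domestic animal, plant, or other (grit / artificial matter).
"""

from __future__ import annotations

from importlib import resources

from .core_io import CompositionTable, read_composition

SPECIES_A = "asian_palm_civet"
SPECIES_B = "small_indian_civet"

#: number of scats behind each FO column (used by exact-replay simulation)
SCAT_COUNTS = {SPECIES_A: 108, SPECIES_B: 44}

#: items-per-scat ranges observed for each species
ITEMS_PER_SCAT = {SPECIES_A: (1, 5), SPECIES_B: (1, 3)}


def load_plnp_composition() -> CompositionTable:
    """The packaged civet diet composition table (FO counts per species)."""
    path = resources.files("civetniche.data") / "plnp_composition.csv"
    with resources.as_file(path) as p:
        return read_composition(p)
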