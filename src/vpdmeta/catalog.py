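"""Trait catalog for the VPD study database.

The meta-analysis covers 59 plant traits and physiological variables,
organised in four groups (leaf gas exchange / development / anatomy; leaf
hormonal, carbohydrate and mineral status; whole-plant mass, development and
architecture; yield and reproductive development).  The catalog carries, for
each trait, its group, a short description, and the reference number of
studies (n) and species (N) contributing to it in the source database —
the latter two drive the paper-like synthetic scenario.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

GROUP_GAS_EXCHANGE = "leaf_gas_exchange_development_anatomy"
GROUP_BIOCHEMICAL = "leaf_hormonal_carbohydrate_mineral"
GROUP_WHOLE_PLANT = "whole_plant_mass_development_architecture"
GROUP_REPRODUCTIVE = "yield_reproductive_development"

#: Traits measured in a gas-exchange cuvette, where the SC/DC
#: measurement-condition distinction (same vs. different cuvette conditions
#: across growth treatments) is meaningful.
GAS_EXCHANGE_TRAITS = frozenset(
    {"leaf_transpiration_rate", "stomatal_conductance", "photosynthetic_rate"}
)

#: Traits for which no study in the source database reported a usable SD;
#: these fall back to unit weighting.
ALL_MISSING_SD_TRAITS = frozenset(
    {"air_space_fraction_in_leaf", "length_of_mesophyll_cell", "time_to_anther_opening"}
)


@dataclass(frozen=True)
class TraitEntry:
    name: str
    group: str
    description: str
    n_studies: int  # reference study count in the source database
    n_species: int  # reference species count


# (name, group, description, n studies, N species)
_TABLE = [
    ("whole_plant_transpiration_rate", GROUP_GAS_EXCHANGE, "Whole-plant water loss measured gravimetrically", 38, 21),
    ("leaf_transpiration_rate", GROUP_GAS_EXCHANGE, "Single-leaf gas exchange via IRGA system", 31, 25),
    ("stomatal_conductance", GROUP_GAS_EXCHANGE, "Leaf conductance to H2O using IRGA/porometer", 62, 35),
    ("photosynthetic_rate", GROUP_GAS_EXCHANGE, "Single-leaf gas exchange via IRGA system", 36, 25),
    ("leaf_area", GROUP_GAS_EXCHANGE, "Measured on one or more representative leaves", 62, 36),
    ("leaf_expansion_rate", GROUP_GAS_EXCHANGE, "Rate of leaf expansion per unit of time", 4, 2),
    ("leaf_dry_mass", GROUP_GAS_EXCHANGE, "Mass of oven-dried leaves", 21, 11),
    ("specific_leaf_area", GROUP_GAS_EXCHANGE, "Ratio of leaf area to its mass", 37, 26),
    ("stomatal_size", GROUP_GAS_EXCHANGE, "Stomatal dimensions", 27, 10),
    ("stomatal_density", GROUP_GAS_EXCHANGE, "Stomata number per unit area", 37, 22),
    ("stomatal_index", GROUP_GAS_EXCHANGE, "Number of stomata relative to epidermal cells", 15, 7),
    ("trichome_density", GROUP_GAS_EXCHANGE, "Number of trichomes per unit area", 1, 1),
    ("epicuticular_wax", GROUP_GAS_EXCHANGE, "Amount of leaf epicuticular wax", 2, 2),
    ("epidermal_cell_size", GROUP_GAS_EXCHANGE, "Epidermal cell dimensions", 9, 9),
    ("vein_density", GROUP_GAS_EXCHANGE, "Number of veins per unit area", 2, 2),
    ("leaf_thickness", GROUP_GAS_EXCHANGE, "Leaf thickness measured by microscope", 10, 10),
    ("air_space_fraction_in_leaf", GROUP_GAS_EXCHANGE, "Intercellular air space in spongy mesophyll", 5, 5),
    ("spongy_mesophyll_cell_number", GROUP_GAS_EXCHANGE, "Spongy mesophyll cells per unit area", 2, 2),
    ("length_of_mesophyll_cell", GROUP_GAS_EXCHANGE, "Length of palisade mesophyll cells", 4, 4),
    ("leaf_aba", GROUP_BIOCHEMICAL, "Abscisic acid concentration in the leaf", 13, 6),
    ("leaf_starch", GROUP_BIOCHEMICAL, "Starch content in the leaf", 4, 3),
    ("leaf_soluble_carbohydrates", GROUP_BIOCHEMICAL, "Soluble carbohydrates in the leaf", 4, 3),
    ("leaf_n", GROUP_BIOCHEMICAL, "Nitrogen content in the leaf", 24, 17),
    ("leaf_p", GROUP_BIOCHEMICAL, "Phosphorus content in the leaf", 14, 6),
    ("leaf_k", GROUP_BIOCHEMICAL, "Potassium content in the leaf", 14, 7),
    ("leaf_ca", GROUP_BIOCHEMICAL, "Calcium content in the leaf", 20, 14),
    ("leaf_mg", GROUP_BIOCHEMICAL, "Magnesium content in the leaf", 7, 6),
    ("leaf_fe", GROUP_BIOCHEMICAL, "Iron content in the leaf", 3, 2),
    ("leaf_na", GROUP_BIOCHEMICAL, "Sodium content in the leaf", 6, 4),
    ("leaf_s", GROUP_BIOCHEMICAL, "Sulfur content in the leaf", 3, 3),
    ("leaf_zn", GROUP_BIOCHEMICAL, "Zinc content in the leaf", 2, 2),
    ("leaf_mo", GROUP_BIOCHEMICAL, "Molybdenum content in the leaf", 1, 1),
    ("leaf_b", GROUP_BIOCHEMICAL, "Boron content in the leaf", 2, 2),
    ("leaf_v", GROUP_BIOCHEMICAL, "Vanadium content in the leaf", 2, 2),
    ("leaf_methionine", GROUP_BIOCHEMICAL, "Methionine content in the leaf", 1, 1),
    ("leaf_alpha_aminobutyric_acid", GROUP_BIOCHEMICAL, "Alpha-aminobutyric acid in the leaf", 1, 1),
    ("leaf_glutamine", GROUP_BIOCHEMICAL, "Glutamine content in the leaf", 1, 1),
    ("leaf_threonine", GROUP_BIOCHEMICAL, "Threonine content in the leaf", 1, 1),
    ("leaf_allothreonine", GROUP_BIOCHEMICAL, "Allothreonine content in the leaf", 1, 1),
    ("whole_plant_dry_mass", GROUP_WHOLE_PLANT, "Total mass of oven-dried stems, leaves, roots", 36, 25),
    ("shoot_dry_mass", GROUP_WHOLE_PLANT, "Mass of oven-dried stems and leaves", 80, 62),
    ("root_dry_mass", GROUP_WHOLE_PLANT, "Mass of oven-dried root systems or fine roots", 30, 15),
    ("plant_height", GROUP_WHOLE_PLANT, "Plant height measured from the collar", 61, 47),
    ("leaf_number", GROUP_WHOLE_PLANT, "Total number of leaves per plant", 32, 22),
    ("number_of_branches_and_tillers", GROUP_WHOLE_PLANT, "Branches and tillers per plant", 3, 3),
    ("diameter_of_stem_base", GROUP_WHOLE_PLANT, "Stem diameter measured near the soil", 2, 2),
    ("pct_leaves_wide_insertion_angle", GROUP_WHOLE_PLANT, "Leaves with insertion angle > 67 deg (%)", 1, 1),
    ("pct_leaves_narrow_insertion_angle", GROUP_WHOLE_PLANT, "Leaves with insertion angle < 22 deg (%)", 1, 1),
    ("fractional_radiation_interception", GROUP_WHOLE_PLANT, "Transmitted over incident shortwave radiation", 1, 1),
    ("yield", GROUP_REPRODUCTIVE, "Fruit, grain, leaf, root yields of crop plants", 25, 12),
    ("number_of_flowers", GROUP_REPRODUCTIVE, "Flowers or flowering buds per plant", 12, 8),
    ("number_of_bracts", GROUP_REPRODUCTIVE, "Bracts per plant", 1, 1),
    ("flower_size", GROUP_REPRODUCTIVE, "Dimensions of flowers", 1, 1),
    ("time_to_flowering", GROUP_REPRODUCTIVE, "Time from experiment initiation to flowering", 8, 8),
    ("time_to_anther_opening", GROUP_REPRODUCTIVE, "Hours until most or all anthers are open", 9, 4),
    ("sugar_in_fruit", GROUP_REPRODUCTIVE, "Total sugar content in fruit", 2, 1),
    ("k_in_fruit_or_flower", GROUP_REPRODUCTIVE, "Potassium in the fruit or flower", 3, 2),
    ("ca_in_fruit_or_flower", GROUP_REPRODUCTIVE, "Calcium in the fruit or flower", 3, 2),
    ("methionine_in_fruit", GROUP_REPRODUCTIVE, "Methionine in the fruit or flower", 1, 1),
]


class TraitCatalog(Mapping[str, TraitEntry]):
    """Immutable mapping of trait name -> :class:`TraitEntry`."""

    def __init__(self, entries: list[TraitEntry]):
        self._entries = {e.name: e for e in entries}
        if len(self._entries) != len(entries):
            raise ValueError("duplicate trait names in catalog")

    def __getitem__(self, name: str) -> TraitEntry:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for e in self._entries.values():
            out.setdefault(e.group, []).append(e.name)
        return out


def default_catalog() -> TraitCatalog:
    """The packaged 59-trait catalog."""
    return TraitCatalog([TraitEntry(*row) for row in _TABLE])
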