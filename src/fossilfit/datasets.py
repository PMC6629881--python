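"""Packaged reference fixtures.

Small delimited tables shipped with the package:

* the trait values of the middle-Miocene oreochromine fossil
  (†*Oreochromimos kabchorensis*) as printed in its published description —
  vertebral counts, fin formulas, lacrimal tubule and supraneural counts,
  scale characters;
* a *partial* genus-level reference table for *Alcolapia* and *Oreochromis*
  limited to the trait ranges printed in the running literature (provenance
  column cites the original sources). Ranges the literature survey did not
  print are simply absent (treated as unknown), so this table demonstrates
  the comparison machinery; it is not the full published range compilation.

Synthetic stand-ins for anything beyond these printed values come from
:mod:`fossilfit.synthetic_data`, never from this module.
"""

from __future__ import annotations

from importlib.resources import files

from .bestfit import (
    FossilObservation,
    ReferenceTraitTable,
    read_fossil_observation,
    read_reference_table,
)

__all__ = ["fossil_observation", "oreochromini_genus_table"]


def _data(name: str):
    return files("fossilfit") / "data" / name


def fossil_observation() -> FossilObservation:
    """Observed traits of the fossil as printed in its description."""
    return read_fossil_observation(str(_data("oreochromimos_fossil.tsv")))


def oreochromini_genus_table() -> ReferenceTraitTable:
    """Partial genus-level ranges for Alcolapia and Oreochromis (printed values only)."""
    return read_reference_table(str(_data("oreochromini_genera.tsv")))
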