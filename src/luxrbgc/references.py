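"""Synthetic LuxR reference panel (programmatically generated stand-in).

Real LuxR-family reference proteins (LuxR, LasR, TraR, PhzR, BjaR, ... on
the AHL-responsive side; OryR and NesR on the plant-responsive side; GerE
as the DNA-binding-domain-only outgroup) cannot be bundled here, so this
module generates a synthetic panel that reproduces the *structural facts*
the pipeline relies on:

- all panel members share a common LuxR-like scaffold and align gaplessly;
- two diagnostic alignment columns separate the subfamilies: AHL-responsive
  references carry the AHL consensus residues there, plant-responsive
  references carry M at the first and W at the second;
- the GerE-like outgroup is far more divergent than any ingroup pair, so
  outgroup rooting behaves as it would with the real sequences.

Every sequence is synthetic; only the *names* follow the field's usual
reference-protein naming.  Deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import mutate_protein, random_protein

#: AHL-responsive reference names (synthetic sequences, field-standard names)
AHL_REFERENCE_NAMES = (
    "LuxR_ref", "LasR_ref", "TraR_ref", "PhzR_ref", "BjaR_ref", "RpaR_ref",
    "YenR_ref", "EsaR_ref", "SdiA_ref", "RhlR_ref", "BpsR_ref", "BraR_ref",
)
#: plant-responsive reference names
PLANT_REFERENCE_NAMES = ("OryR_ref", "NesR_ref")
OUTGROUP_NAME = "GerE_ref"

PANEL_LENGTH = 250
#: diagnostic columns (0-based, within the gapless panel alignment)
DIAGNOSTIC_COLUMNS = (78, 112)
#: residues at the diagnostic columns: AHL consensus vs plant-responsive M/W
AHL_DIAGNOSTIC = ("L", "Y")
PLANT_DIAGNOSTIC = ("M", "W")

_PANEL_SEED = 20180327  # fixed: the panel is a constant of the package


@dataclass(frozen=True)
class ReferencePanel:
    """Aligned reference set with marked diagnostic columns."""

    sequences: dict[str, str]          # name -> (gapless) aligned sequence
    labels: dict[str, str]             # name -> "ahl" | "plant" | "outgroup"
    diagnostic_columns: tuple[int, int]

    @property
    def ahl_names(self) -> list[str]:
        return [n for n, l in self.labels.items() if l == "ahl"]

    @property
    def plant_names(self) -> list[str]:
        return [n for n, l in self.labels.items() if l == "plant"]

    def ahl_consensus(self) -> tuple[str, str]:
        """Most common residue of the AHL references at each diagnostic column."""
        c1, c2 = self.diagnostic_columns
        out = []
        for col in (c1, c2):
            residues = [self.sequences[n][col] for n in self.ahl_names]
            out.append(max(set(residues), key=residues.count))
        return tuple(out)  # type: ignore[return-value]


def reference_panel(seed: int = _PANEL_SEED) -> ReferencePanel:
    """Build the synthetic reference panel.

    AHL references are ~75% identical mutants of a common scaffold pinned
    to the AHL consensus at the diagnostic columns; plant-responsive
    references come from a sister scaffold pinned to M/W; the GerE-like
    outgroup shares only ~35% identity with the scaffold.
    """
    rng = np.random.default_rng(seed)
    scaffold = random_protein(PANEL_LENGTH, rng)
    c1, c2 = DIAGNOSTIC_COLUMNS

    def pin(seq: str, residues: tuple[str, str]) -> str:
        chars = list(seq)
        chars[c1], chars[c2] = residues
        return "".join(chars)

    sequences: dict[str, str] = {}
    labels: dict[str, str] = {}
    for name in AHL_REFERENCE_NAMES:
        sequences[name] = pin(mutate_protein(scaffold, 0.75, rng), AHL_DIAGNOSTIC)
        labels[name] = "ahl"
    plant_scaffold = mutate_protein(scaffold, 0.60, rng)
    for name in PLANT_REFERENCE_NAMES:
        sequences[name] = pin(mutate_protein(plant_scaffold, 0.85, rng), PLANT_DIAGNOSTIC)
        labels[name] = "plant"
    sequences[OUTGROUP_NAME] = mutate_protein(scaffold, 0.35, rng)
    labels[OUTGROUP_NAME] = "outgroup"
    return ReferencePanel(sequences, labels, DIAGNOSTIC_COLUMNS)
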