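"""Tabulation of screen results and diagnostic-residue LuxR classification.

Summaries mirror the published presentation: proportions of cluster types,
LuxI co-occurrence, habitats and taxonomic classes over the dereplicated
hit list, and per-type association frequency (hits among all clusters of a
type) over the full input population.

LuxR subfamily classification uses two diagnostic alignment positions of
the signal-binding domain: plant-responsive regulators carry M and W at
the first and second position respectively, canonical AHL-responsive
regulators carry their own consensus there, and a protein matching neither
pattern is called atypical (as for the telomycin-cluster regulator).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .dereplication import AlignmentScoring, global_align
from .mining import LuxRAssociation
from .records import BGCRecord
from .references import ReferencePanel, reference_panel

logger = logging.getLogger(__name__)


class LuxRClass(str, enum.Enum):
    AHL_TYPE = "AHL_type"
    PLANT_RESPONSIVE_LIKE = "plant_responsive_like"
    ATYPICAL = "atypical"


def display_round(pct: float) -> float:
    """Paper-style mixed display precision: 1 decimal at >= 1%, 2 below."""
    return round(pct, 1) if pct >= 1.0 else round(pct, 2)


@dataclass
class SummaryReport:
    """Results-section style summary of a (dereplicated) hit list."""

    n_hits_unfiltered: int
    n_hits_dereplicated: int
    pct_with_luxi: float
    type_proportions: dict[str, float] = field(default_factory=dict)
    habitat_proportions: dict[str, float] = field(default_factory=dict)
    class_proportions: dict[str, float] = field(default_factory=dict)
    per_type_association: dict[str, tuple[int, int, float]] = field(
        default_factory=dict
    )

    def to_dict(self) -> dict:
        return {
            "n_hits_unfiltered": self.n_hits_unfiltered,
            "n_hits_dereplicated": self.n_hits_dereplicated,
            "pct_with_luxi": self.pct_with_luxi,
            "pct_with_luxi_display": display_round(self.pct_with_luxi),
            "type_proportions": {
                k: display_round(v) for k, v in self.type_proportions.items()
            },
            "habitat_proportions": {
                k: display_round(v) for k, v in self.habitat_proportions.items()
            },
            "class_proportions": {
                k: display_round(v) for k, v in self.class_proportions.items()
            },
            "per_type_association": {
                k: {"hits": h, "total": t, "percent": display_round(p)}
                for k, (h, t, p) in self.per_type_association.items()
            },
        }


def _proportions(values: Sequence[str]) -> dict[str, float]:
    if not values:
        return {}
    out: dict[str, float] = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return {k: 100.0 * c / len(values) for k, c in sorted(out.items())}


def tabulate(
    associations: Sequence[LuxRAssociation],
    records: Mapping[str, BGCRecord],
    n_hits_unfiltered: int | None = None,
) -> SummaryReport:
    """Summarize a hit list: LuxI co-occurrence, type/habitat/class mix.

    Proportions are computed over ``associations`` (normally the
    dereplicated list).  Empty input yields a zeroed report, not an error.
    Permutation-invariant in the order of ``associations``.
    """
    n = len(associations)
    if n == 0:
        return SummaryReport(
            n_hits_unfiltered=n_hits_unfiltered or 0,
            n_hits_dereplicated=0,
            pct_with_luxi=0.0,
        )
    with_luxi = sum(1 for a in associations if a.has_luxi)
    recs = [records[a.record_id] for a in associations]
    return SummaryReport(
        n_hits_unfiltered=n if n_hits_unfiltered is None else n_hits_unfiltered,
        n_hits_dereplicated=n,
        pct_with_luxi=100.0 * with_luxi / n,
        type_proportions=_proportions([a.bgc_type for a in associations]),
        habitat_proportions=_proportions([r.habitat.value for r in recs]),
        class_proportions=_proportions([r.taxon_class for r in recs]),
    )


def association_frequency(
    total_by_type: Mapping[str, int], hits_by_type: Mapping[str, int]
) -> dict[str, float]:
    """Percent of all clusters of each type that are LuxR-associated.

    Types with zero total are omitted; a type with more hits than total
    clusters is an input error.
    """
    out: dict[str, float] = {}
    for bgc_type, total in total_by_type.items():
        if total == 0:
            continue
        hits = hits_by_type.get(bgc_type, 0)
        if hits > total:
            raise ValueError(
                f"{bgc_type}: {hits} hits exceed {total} total clusters"
            )
        out[bgc_type] = 100.0 * hits / total
    return out


def classify_luxr(
    seq: str,
    panel: ReferencePanel | None = None,
    scoring: AlignmentScoring | None = None,
) -> LuxRClass:
    """Classify a LuxR protein by its two diagnostic residues.

    The query is globally aligned to its nearest panel reference (highest
    alignment score); the query residues aligned to the reference's two
    diagnostic columns are read off.  W at the second position calls the
    protein plant-responsive-like (M at the first strengthens the call but
    is not required); matching the AHL consensus at both positions calls it
    AHL-type; anything else — including gaps at both positions — is
    atypical.
    """
    panel = panel or reference_panel()
    ingroup = [n for n, l in panel.labels.items() if l != "outgroup"]
    best_name, best_result = None, None
    for name in ingroup:
        a, b, score = global_align(seq, panel.sequences[name], scoring)
        if best_result is None or score > best_result[2]:
            best_name, best_result = name, (a, b, score)
    aligned_q, aligned_r, _ = best_result

    # map reference diagnostic columns through the alignment
    ref_pos = -1
    residues: dict[int, str] = {}
    for qc, rc in zip(aligned_q, aligned_r):
        if rc != "-":
            ref_pos += 1
            if ref_pos in panel.diagnostic_columns:
                residues[ref_pos] = qc
    c1, c2 = panel.diagnostic_columns
    r1, r2 = residues.get(c1, "-"), residues.get(c2, "-")

    if r1 == "-" and r2 == "-":
        logger.warning(
            "query aligns with gaps at both diagnostic columns (vs %s); "
            "calling atypical",
            best_name,
        )
        return LuxRClass.ATYPICAL
    if r2 == "W":
        return LuxRClass.PLANT_RESPONSIVE_LIKE
    if (r1, r2) == panel.ahl_consensus():
        return LuxRClass.AHL_TYPE
    return LuxRClass.ATYPICAL
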