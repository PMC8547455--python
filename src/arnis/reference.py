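"""Published reference observations from the coastal Adriatic experiment.

These are printed summary values from the Kaštela Bay grazer-removal /
phosphate-amendment study around which this pipeline was designed: the
seawater characteristics at the start of the incubation, the microscopy
abundance endpoints per treatment, and the per-taxon fold-change table
with its published response-group assignments.  They serve as fixed
inputs for arithmetic cross-checks and for validating the response
classifier against an independent, hand-curated grouping.

Units: cell abundances are cells per liter (seawater table) or cells per
ml (incubation endpoints); nutrient totals are umol per liter.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SEAWATER",
    "ABUNDANCE_ENDPOINTS",
    "AAP_FILTRATION",
    "RESPONSE_TABLE",
    "ReferenceResponseRow",
]

#: initial seawater characteristics (subset used by the cross-checks)
SEAWATER = {
    "n_total_umol_per_l": 8.286,
    "p_total_umol_per_l": 0.055,
    "heterotrophic_bacteria_cells_per_l": 52.1e7,
    "cyanobacteria_cells_per_l": 2.87e7,
    "aap_bacteria_cells_per_l": 5.5e7,
}

#: total bacterial abundance endpoints (cells ml^-1) per treatment:
#: (t_start_h, n_start, t_end_h, n_end) from epifluorescence counts
ABUNDANCE_ENDPOINTS = {
    "F": (0.0, 0.26e6, 48.0, 1.56e6),
    "FP": (0.0, 0.22e6, 60.0, 1.79e6),
    "C": (0.0, 0.47e6, 60.0, 0.85e6),
}

#: aerobic anoxygenic phototroph (AAP) abundance before/after 1.2-um
#: prefiltration (cells ml^-1), and the total bacterial abundance of the
#: filtered treatment at time zero used to express AAP as a percentage
AAP_FILTRATION = {
    "aap_initial_cells_per_ml": 5.5e4,
    "aap_filtered_cells_per_ml": 1.4e4,
    "total_filtered_cells_per_ml": 0.26e6,
}


@dataclass(frozen=True)
class ReferenceResponseRow:
    """One taxon of the published response table.

    ``fc_f_over_c`` is None where the control rate could not be computed
    (the taxon vanished after filtration).  ``borderline`` marks the two
    rows the original analysis itself flagged as borderline between
    groups.  Shares are percent of reads at 24 h per treatment.
    """

    taxon: str
    group: str  # published response-group heading
    share_c: float
    share_f: float
    share_fp: float
    fc_f_over_c: float | None
    fc_fp_over_f: float
    borderline: bool = False


RESPONSE_TABLE: tuple[ReferenceResponseRow, ...] = (
    ReferenceResponseRow("Saccharospirillaceae", "I", 0.05, 2.98, 4.45, 5.36, 1.52),
    ReferenceResponseRow("Campylobacterales", "I", 0.04, 0.22, 0.38, 6.75, 1.62),
    ReferenceResponseRow("Polaribacter", "I", 3.03, 0.67, 0.70, 3.57, 1.76),
    ReferenceResponseRow("Oceanospirillales", "I", 7.08, 5.30, 6.90, 3.45, 1.53),
    ReferenceResponseRow("Alteromonadales", "I", 7.27, 77.51, 77.16, 3.07, 1.90),
    ReferenceResponseRow("NS3a marine group", "I", 0.59, 0.31, 0.33, 2.90, 1.63),
    ReferenceResponseRow("Spongiispira", "I", 0.05, 2.63, 3.93, 2.74, 1.75),
    ReferenceResponseRow("Rhodospirillales", "I", 0.14, 0.12, 0.15, 2.2, 1.66),
    ReferenceResponseRow("OM60(NOR5)", "I", 7.31, 0.59, 0.54, 2.08, 1.52),
    ReferenceResponseRow("Burkholderiales", "I", 0.78, 0.12, 0.10, 2.02, 1.93),
    ReferenceResponseRow("Other Flavobacteriales", "I", 1.04, 1.03, 1.09, 2.02, 2.16),
    ReferenceResponseRow("Pirellulales", "I", 1.45, 0.02, 0.01, 2.05, 1.54),
    ReferenceResponseRow("Cellvibrionales", "I", 7.79, 0.60, 0.57, 1.82, 1.56),
    ReferenceResponseRow("SAR86", "I", 0.55, 0.18, 0.22, 1.79, 1.54),
    ReferenceResponseRow("Caulobacterales", "I", 2.08, 0.02, 0.02, None, 1.78),
    ReferenceResponseRow("Flavobacteriales, all", "I", 32.61, 2.18, 2.36, 1.51, 2.63),
    ReferenceResponseRow("KI89A clade", "I", 0.34, 0.04, 0.03, 1.49, 1.80),
    ReferenceResponseRow(
        "SAR116", "III", 1.09, 0.24, 0.25, 1.35, 1.49, borderline=True
    ),
    ReferenceResponseRow("Cytophagales", "III", 0.24, 0.03, 0.03, 1.13, 2.48),
    ReferenceResponseRow("SAR92", "III", 0.26, 0.00, 0.02, 1.12, 1.75),
    ReferenceResponseRow(
        "Flavobacteriales, NS groups", "III", 21.97, 1.13, 1.24, 1.10, 2.93
    ),
    ReferenceResponseRow("Rickettsiales", "III", 0.11, 0.02, 0.01, 1.04, 2.79),
    ReferenceResponseRow("Bacteriovoracales", "III", 0.026, 0.003, 0.001, 0.92, 2.10),
    ReferenceResponseRow("SAR11 clade", "III", 0.97, 0.46, 0.57, 0.90, 2.98),
    ReferenceResponseRow("Thiotrichales", "III", 0.35, 0.04, 0.05, 0.91, 2.86),
    ReferenceResponseRow("Balneolales", "III", 1.53, 0.10, 0.13, 0.86, 2.51),
    ReferenceResponseRow(
        "Nereida", "II", 3.04, 8.69, 7.98, 5.90, 1.39, borderline=True
    ),
    ReferenceResponseRow("Rhodobacterales", "II", 12.60, 12.27, 10.71, 5.33, 1.28),
    ReferenceResponseRow("Rhizobiales", "II", 2.60, 0.07, 0.05, 5.12, 1.07),
    ReferenceResponseRow("Sphingomonadales", "II", 0.61, 0.02, 0.01, 3.64, 0.67),
)
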