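"""Bacterial-DNA contamination estimation from marker-gene read fractions.

A virus-like-particle (VLP) preparation is never perfectly free of bacterial
chromosomal DNA. Because a marker locus (the rRNA operon, or the conserved
549-567 bp universal-target segment of the single-copy chaperonin gene cpn60)
occupies a known, tiny fraction of a typical bacterial genome, the fraction of
shotgun reads aligning to that marker can be scaled up to an estimate of the
fraction of *all* DNA in the sample that is of bacterial chromosomal origin:

    bacterial_dna_fraction = read_fraction / (copies * marker_length / genome_size)

Under the defaults (4 Mb genome, 5 kb rRNA operon x 4 copies) a 0.04% rRNA
read fraction implies ~8% bacterial DNA; a 0.00077% cpn60 fraction implies
~5.5%. Raw estimates above 1 are capped at 1 and flagged, since heavily
contaminated samples routinely push the linear conversion past unity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "MarkerModel",
    "RRNA_MODEL",
    "CPN60_MODEL",
    "RRNA_FLAG_THRESHOLD",
    "BacterialFractionEstimate",
    "estimate_bacterial_fraction",
    "contamination_report",
]

#: Read-fraction level above which rRNA contamination is considered
#: non-negligible (the 0.02% screening rule).
RRNA_FLAG_THRESHOLD = 2e-4


@dataclass(frozen=True)
class MarkerModel:
    """A marker locus used as a proxy for bacterial chromosomal DNA.

    ``marker_fraction_of_genome`` is the fraction of a genome's length made up
    of marker copies; dividing an observed marker read fraction by it converts
    reads-on-marker into genome-equivalents of bacterial DNA.
    """

    name: str
    marker_length: int
    copies_per_genome: int
    genome_size: int

    def __post_init__(self) -> None:
        if self.marker_length < 1:
            raise ValueError("marker_length must be >= 1")
        if self.copies_per_genome < 1:
            raise ValueError("copies_per_genome must be >= 1")
        if self.genome_size < self.copies_per_genome * self.marker_length:
            raise ValueError("genome_size must accommodate all marker copies")

    @property
    def marker_fraction_of_genome(self) -> float:
        return self.copies_per_genome * self.marker_length / self.genome_size


#: Typical gut bacterial symbiont: 4 Mb genome, ~5 kb rRNA operon in 4 copies.
RRNA_MODEL = MarkerModel("rRNA", marker_length=5000, copies_per_genome=4, genome_size=4_000_000)

#: cpn60 universal target: single copy, 549-567 bp segment (558 = midpoint).
CPN60_MODEL = MarkerModel("cpn60", marker_length=558, copies_per_genome=1, genome_size=4_000_000)


class BacterialFractionEstimate(NamedTuple):
    fraction: float
    capped: bool


def estimate_bacterial_fraction(
    read_fraction: float, marker: MarkerModel
) -> BacterialFractionEstimate:
    """Convert a marker read fraction into a bacterial-DNA fraction.

    Linear in ``read_fraction`` below the cap; values whose raw conversion
    exceeds 1 are capped at 1.0 with ``capped=True``.
    """
    if not 0.0 <= read_fraction <= 1.0:
        raise ValueError(f"read_fraction must be in [0, 1], got {read_fraction}")
    raw = read_fraction / marker.marker_fraction_of_genome
    if raw > 1.0:
        return BacterialFractionEstimate(1.0, True)
    return BacterialFractionEstimate(raw, False)


def contamination_report(
    marker_fractions: pd.DataFrame,
    models: Mapping[str, MarkerModel],
    rrna_flag_threshold: float = RRNA_FLAG_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample bacterial-DNA estimates plus per-marker cohort summaries.

    Parameters
    ----------
    marker_fractions
        Long table with columns ``sample_id``, ``marker``, ``read_fraction``.
    models
        Marker name -> MarkerModel for every marker appearing in the table.
    rrna_flag_threshold
        Read-fraction threshold above which an rRNA measurement is flagged as
        non-negligible contamination (default 0.02%).

    Returns
    -------
    (per_sample, per_marker)
        ``per_sample``: one row per (sample, marker) with the estimated
        bacterial-DNA fraction, cap flag and rRNA threshold flag.
        ``per_marker``: median and IQR of read fractions and estimates,
        linear interpolation between order statistics.
    """
    required = {"sample_id", "marker", "read_fraction"}
    if not required.issubset(marker_fractions.columns):
        raise ValueError(f"marker fraction table needs columns {sorted(required)}")
    if marker_fractions.empty:
        empty_cols = [
            "sample_id", "marker", "read_fraction",
            "bacterial_fraction", "capped", "flagged",
        ]
        return (
            pd.DataFrame(columns=empty_cols),
            pd.DataFrame(
                columns=["marker", "n", "median_read_fraction", "iqr_read_fraction",
                         "median_bacterial_fraction", "iqr_bacterial_fraction"]
            ),
        )

    rows = []
    for row in marker_fractions.itertuples(index=False):
        marker_name = str(row.marker)
        if marker_name not in models:
            raise KeyError(f"no MarkerModel provided for marker {marker_name!r}")
        frac = float(row.read_fraction)
        est = estimate_bacterial_fraction(frac, models[marker_name])
        flagged = marker_name == "rRNA" and frac > rrna_flag_threshold
        rows.append(
            {
                "sample_id": str(row.sample_id),
                "marker": marker_name,
                "read_fraction": frac,
                "bacterial_fraction": est.fraction,
                "capped": est.capped,
                "flagged": flagged,
            }
        )
    per_sample = pd.DataFrame(rows)

    summaries = []
    for marker_name, grp in per_sample.groupby("marker", sort=True):
        rf = grp["read_fraction"].to_numpy()
        bf = grp["bacterial_fraction"].to_numpy()
        q1_rf, med_rf, q3_rf = np.percentile(rf, [25, 50, 75])
        q1_bf, med_bf, q3_bf = np.percentile(bf, [25, 50, 75])
        summaries.append(
            {
                "marker": marker_name,
                "n": len(grp),
                "median_read_fraction": med_rf,
                "iqr_read_fraction": q3_rf - q1_rf,
                "median_bacterial_fraction": med_bf,
                "iqr_bacterial_fraction": q3_bf - q1_bf,
            }
        )
    return per_sample, pd.DataFrame(summaries)
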