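"""Absolute viral load estimation from an exogenous spike-in phage.

A known titre S (pfu per gram) of an exogenous phage — lactococcal phage Q33,
genome 31.1 kb — is added to the faecal homogenate before nucleic acid
extraction. After sequencing, the fraction f of reads aligning to the spike
genome calibrates the whole sample: under equal genome sizes the total
endogenous load per gram is

    N_total = S * (1 - f) / f

(the spike's own reads are excluded from the endogenous pool). When
per-feature read counts c_i and genome lengths L_i are available the
length-aware estimator corrects each feature's read yield for its genome
size:

    N_total = sum_i S * (c_i / c_s) * (L_s / L_i)

which reduces exactly to the equal-size formula when all L_i = L_s. A
calibration series across several titres checks linearity of spike read
percentage against titre (ordinary least squares, unadjusted R^2, natural
units).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_io import CountMatrix

__all__ = [
    "SpikeConfig",
    "SpikeCalibration",
    "LoadEstimate",
    "SpikeDropoutError",
    "spike_fraction",
    "fit_calibration",
    "estimate_total_load",
    "load_summary",
]

#: Single-titre spiking concentration found to give well-behaved read
#: recovery (pfu per gram).
RECOMMENDED_TITRE = 1e6


class SpikeDropoutError(ValueError):
    """Raised when the spike recovered zero reads: the load is inestimable."""


@dataclass(frozen=True)
class SpikeConfig:
    """Identity and titre series of the spike-in standard."""

    spike_feature_id: str
    spike_genome_length: int = 31_100
    titres: tuple[float, ...] = (1e5, 1e6, 1e7)

    def __post_init__(self) -> None:
        if self.spike_genome_length <= 0:
            raise ValueError("spike_genome_length must be positive")
        if any(t <= 0 for t in self.titres):
            raise ValueError("calibration titres must be strictly positive")


@dataclass(frozen=True)
class SpikeCalibration:
    """OLS fit of spike read percentage against spiked titre."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")


@dataclass(frozen=True)
class LoadEstimate:
    """Per-point absolute loads with their log10 summary.

    ``sd_undefined`` flags a single-point estimate, whose sample SD does not
    exist (reported as 0.0).
    """

    loads: tuple[float, ...]
    log10_mean: float
    log10_sd: float
    sd_undefined: bool = False


def spike_fraction(
    counts: CountMatrix, sample_id: str, spike_feature_id: Optional[str] = None
) -> float:
    """Fraction of a sample's reads assigned to the spike feature.

    A zero-count spike raises :class:`SpikeDropoutError` — mirroring a spike
    that failed to be recovered at all (as happens for RNA phage spikes with a
    DNA-virome protocol), for which no load can be estimated.
    """
    feature = spike_feature_id or counts.spike_feature_id
    if feature is None:
        raise ValueError("no spike feature designated")
    i = counts.sample_index(sample_id)
    j = counts.feature_index(feature)
    total = int(counts.counts[i].sum())
    if total == 0:
        raise ValueError(f"sample {sample_id!r} has zero total reads")
    spike = int(counts.counts[i, j])
    if spike == 0:
        raise SpikeDropoutError(
            f"sample {sample_id!r}: no reads aligned to spike {feature!r}; "
            "load is inestimable"
        )
    return spike / total


def fit_calibration(
    titres: Sequence[float], fractions: Sequence[float]
) -> SpikeCalibration:
    """Ordinary least squares of spike read *percentage* on titre.

    Requires >= 2 distinct titres. R^2 = 1 - SS_res/SS_tot, unadjusted; a
    response with zero variance yields R^2 = 0 by convention.
    """
    x = np.asarray(titres, dtype=float)
    y = 100.0 * np.asarray(fractions, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("titres and fractions must be 1-D and aligned")
    if len(np.unique(x)) < 2:
        raise ValueError("calibration needs >= 2 distinct titres")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 0.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return SpikeCalibration(slope=float(slope), intercept=float(intercept),
                            r_squared=min(r_squared, 1.0))


def estimate_total_load(
    spike_titre: float,
    fraction: float,
    feature_counts: Optional[np.ndarray] = None,
    feature_lengths: Optional[np.ndarray] = None,
    spike_count: Optional[int] = None,
    spike_genome_length: int = 31_100,
) -> float:
    """Estimate total endogenous viral particles per gram from the spike.

    Equal-size mode (default): ``N_total = S * (1 - f) / f``, i.e. every
    endogenous genome is assumed to be the size of the spike genome.

    Length-aware mode (when per-feature ``feature_counts``/``feature_lengths``
    and ``spike_count`` are given): ``N_total = sum_i S * (c_i/c_s) * (L_s/L_i)``
    over endogenous features i, correcting each feature's read yield for its
    genome length. Reduces exactly to equal-size mode when all L_i equal L_s.
    """
    if spike_titre <= 0:
        raise ValueError("spike_titre must be > 0")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"spike fraction must be in (0, 1), got {fraction}")
    if feature_counts is None:
        return spike_titre * (1.0 - fraction) / fraction
    if feature_lengths is None or spike_count is None:
        raise ValueError("length-aware mode needs feature_lengths and spike_count")
    c = np.asarray(feature_counts, dtype=float)
    lengths = np.asarray(feature_lengths, dtype=float)
    if c.shape != lengths.shape:
        raise ValueError("feature_counts and feature_lengths must align")
    if spike_count <= 0:
        raise SpikeDropoutError("zero spike reads; load is inestimable")
    return float(np.sum(spike_titre * (c / spike_count) * (spike_genome_length / lengths)))


def load_summary(per_point_loads: Sequence[float]) -> LoadEstimate:
    """Mean and sample SD of log10 loads across calibration points/replicates."""
    loads = tuple(float(x) for x in per_point_loads)
    if not loads:
        raise ValueError("no loads to summarise")
    if any(x <= 0 for x in loads):
        raise ValueError("loads must be > 0")
    logs = np.log10(loads)
    if len(logs) == 1:
        return LoadEstimate(loads=loads, log10_mean=float(logs[0]),
                            log10_sd=0.0, sd_undefined=True)
    return LoadEstimate(
        loads=loads,
        log10_mean=float(logs.mean()),
        log10_sd=float(logs.std(ddof=1)),
        sd_undefined=False,
    )
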