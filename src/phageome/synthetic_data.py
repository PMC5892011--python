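"""Synthetic communities and contig sets with known ground truth.

The generators emulate the statistical structure that the downstream analyses
assume, so every estimator in the pipeline can be scored against a planted
truth:

* donor-structured phageome abundance profiles (log-normal donor baselines,
  treatment/operator/noise perturbations on the log scale, multinomial read
  sampling with weights proportional to abundance x genome length);
* size-classed circular/linear contig sets, where circular genomes are
  emitted linearized with a terminal direct repeat (the signature the
  circularity detector looks for);
* spiked virus communities with an exogenous internal-standard phage;
* marker read fractions that are the exact inverse of the contamination
  estimator's conversion.

Read sampling weights are particle_count x genome_length: shotgun read yield
is proportional to the total nucleic acid a feature contributes. This is the
assumption under which the equal-genome-size absolute-load formula is exact.
MDA amplification bias toward short circular genomes is not simulated by
default; an optional per-feature multiplicative bias vector can inject it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .contamination import MarkerModel
from .data_io import ContigRecord, CountMatrix, SampleMetadata

__all__ = [
    "CommunitySpec",
    "ParticleCommunity",
    "CommunityTruth",
    "DEFAULT_SIZE_CLASSES",
    "generate_community",
    "generate_contig_set",
    "spike_community",
    "generate_marker_fractions",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class CommunitySpec:
    """Design of a simulated multi-donor phageome experiment.

    All effect sizes are standard deviations on the natural-log abundance
    scale. Defaults describe a storage-style experiment: 4 donors x 6 samples,
    donor individuality dominating (donor_effect_sd=1.0) over a modest
    treatment effect (0.3) and technical noise (0.2).
    """

    n_donors: int = 4
    samples_per_donor: int = 6
    n_features: int = 150
    donor_effect_sd: float = 1.0
    noise_sd: float = 0.2
    treatment_effect_sd: float = 0.3
    operator_effect_sd: float = 0.0
    n_treatments: int = 3
    n_operators: int = 3
    reads_per_sample: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_donors, self.samples_per_donor, self.n_features) < 1:
            raise ValueError("counts must be >= 1")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        for name in ("donor_effect_sd", "noise_sd", "treatment_effect_sd", "operator_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_treatments < 1 or self.n_operators < 1:
            raise ValueError("n_treatments and n_operators must be >= 1")


@dataclass
class CommunityTruth:
    """Latent state of a generated community, sufficient to score estimators."""

    feature_log_base: np.ndarray          # (n_features,)
    genome_lengths: np.ndarray            # (n_features,) bp
    donor_effects: np.ndarray             # (n_donors, n_features)
    treatment_effects: np.ndarray         # (n_treatments, n_features)
    operator_effects: np.ndarray          # (n_operators, n_features)
    sample_noise: np.ndarray              # (n_samples, n_features)
    expected_proportions: np.ndarray      # (n_samples, n_features) read probs
    donor_of_sample: list[str] = field(default_factory=list)
    treatment_of_sample: list[str] = field(default_factory=list)
    operator_of_sample: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ParticleCommunity:
    """A physical virus community: particles per gram plus an optional spike.

    ``spike_genome_length`` defaults to 31,100 bp, the genome size of the
    lactococcal phage Q33 internal standard.
    """

    particle_counts: np.ndarray
    genome_lengths: np.ndarray
    spike_titre: float = 0.0
    spike_genome_length: int = 31_100

    def __post_init__(self) -> None:
        counts = np.asarray(self.particle_counts, dtype=float)
        lengths = np.asarray(self.genome_lengths)
        object.__setattr__(self, "particle_counts", counts)
        object.__setattr__(self, "genome_lengths", lengths)
        if counts.shape != lengths.shape:
            raise ValueError("particle_counts and genome_lengths must align")
        if (counts < 0).any():
            raise ValueError("particle_counts must be >= 0")
        if (lengths <= 0).any():
            raise ValueError("genome_lengths must be positive")
        if self.spike_titre < 0:
            raise ValueError("spike_titre must be >= 0")
        if self.spike_genome_length <= 0:
            raise ValueError("spike_genome_length must be positive")

    @property
    def expected_spike_fraction(self) -> float:
        """S*L_s / (S*L_s + sum N_i*L_i): expected spike read fraction."""
        spike_mass = self.spike_titre * self.spike_genome_length
        endo_mass = float(self.particle_counts @ self.genome_lengths)
        total = spike_mass + endo_mass
        if total == 0:
            raise ValueError("community has zero total nucleic acid")
        return spike_mass / total


def generate_community(
    spec: CommunitySpec,
) -> tuple[CountMatrix, list[SampleMetadata], CommunityTruth]:
    """Simulate a donor-structured phageome count matrix.

    Per-donor baseline log-abundances are drawn once per donor
    (normal, sd=donor_effect_sd) around a shared community profile;
    treatment/operator/noise perturbations are added per sample on the log
    scale; reads are drawn multinomially with probabilities proportional to
    abundance x genome length. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_donors * spec.samples_per_donor

    feature_log_base = rng.normal(0.0, 1.0, spec.n_features)
    genome_lengths = np.rint(
        10 ** rng.uniform(np.log10(3e3), np.log10(1e5), spec.n_features)
    ).astype(np.int64)
    donor_effects = rng.normal(0.0, spec.donor_effect_sd, (spec.n_donors, spec.n_features))
    treatment_effects = rng.normal(
        0.0, spec.treatment_effect_sd, (spec.n_treatments, spec.n_features)
    )
    operator_effects = rng.normal(
        0.0, spec.operator_effect_sd, (spec.n_operators, spec.n_features)
    )
    sample_noise = rng.normal(0.0, spec.noise_sd, (n_samples, spec.n_features))

    counts = np.zeros((n_samples, spec.n_features), dtype=np.int64)
    expected = np.zeros((n_samples, spec.n_features))
    sample_ids, metadata = [], []
    donors, treatments, operators = [], [], []
    s = 0
    for d in range(spec.n_donors):
        for k in range(spec.samples_per_donor):
            t = k % spec.n_treatments
            o = k % spec.n_operators
            log_abund = (
                feature_log_base
                + donor_effects[d]
                + treatment_effects[t]
                + operator_effects[o]
                + sample_noise[s]
            )
            weights = np.exp(log_abund) * genome_lengths
            probs = weights / weights.sum()
            counts[s] = rng.multinomial(spec.reads_per_sample, probs)
            expected[s] = probs
            sample_id = f"d{d}_s{k}"
            sample_ids.append(sample_id)
            donors.append(f"donor{d}")
            treatments.append(f"t{t}")
            operators.append(f"op{o}")
            metadata.append(
                SampleMetadata(
                    sample_id=sample_id,
                    donor=f"donor{d}",
                    treatment=f"t{t}",
                    timepoint=str(t),
                    operator=f"op{o}",
                )
            )
            s += 1

    matrix = CountMatrix(
        sample_ids=sample_ids,
        feature_ids=[f"f{j}" for j in range(spec.n_features)],
        counts=counts,
        feature_lengths=genome_lengths,
    )
    truth = CommunityTruth(
        feature_log_base=feature_log_base,
        genome_lengths=genome_lengths,
        donor_effects=donor_effects,
        treatment_effects=treatment_effects,
        operator_effects=operator_effects,
        sample_noise=sample_noise,
        expected_proportions=expected,
        donor_of_sample=donors,
        treatment_of_sample=treatments,
        operator_of_sample=operators,
    )
    return matrix, metadata, truth


#: Size classes of complete circular contigs seen in gut phageome assemblies:
#: short cryptic plasmids (1-3 kb), Gokushovirinae (~5 kb), other Microviridae
#: (~6.3 kb), temperate Caudovirales (38-46 kb) and crAssphage-like (94-101 kb).
DEFAULT_SIZE_CLASSES: dict[str, tuple[int, int]] = {
    "plasmid_like": (1_000, 3_000),
    "gokushovirinae": (4_700, 5_300),
    "microviridae": (6_000, 6_600),
    "caudovirales": (38_000, 46_000),
    "crass_like": (94_000, 101_000),
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def generate_contig_set(
    n_per_class: int,
    min_repeat: int = 20,
    seed: int = 0,
    size_classes: Mapping[str, tuple[int, int]] = DEFAULT_SIZE_CLASSES,
    class_bias: Optional[Mapping[str, float]] = None,
) -> tuple[list[ContigRecord], pd.DataFrame]:
    """Emit ``n_per_class`` circular and ``n_per_class`` linear contigs per class.

    Circular truth genomes are rotated to a random cut position and emitted
    with their first k bases (k uniform in [min_repeat, 2*min_repeat])
    duplicated at the 3' end; linear contigs carry no planted terminal repeat
    (a chance >=20 bp exact repeat has probability ~ L^2 * 4^-20, negligible).

    ``class_bias`` optionally scales the reported mean coverage per class,
    a hook for emulating MDA over-amplification of small circular genomes.

    Returns the records and a truth table with columns contig_id, size_class,
    circular, true_length, emitted_length, repeat_len, coverage.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    if min_repeat < 10:
        raise ValueError("min_repeat must be >= 10")
    rng = np.random.default_rng(seed)
    records: list[ContigRecord] = []
    truth_rows = []
    for cls, (lo, hi) in size_classes.items():
        bias = 1.0 if class_bias is None else float(class_bias.get(cls, 1.0))
        for circular in (True, False):
            for i in range(n_per_class):
                true_len = int(rng.integers(lo, hi + 1))
                coverage = float(rng.uniform(5.0, 50.0)) * bias
                prefix = "circ" if circular else "lin"
                contig_id = f"{prefix}_{cls}_{i:03d}"
                if circular:
                    genome = _random_seq(rng, true_len)
                    cut = int(rng.integers(0, true_len))
                    rotated = genome[cut:] + genome[:cut]
                    k = int(rng.integers(min_repeat, 2 * min_repeat + 1))
                    seq = rotated + rotated[:k]
                else:
                    k = 0
                    seq = _random_seq(rng, true_len)
                records.append(
                    ContigRecord(contig_id=contig_id, sequence=seq, coverage=coverage)
                )
                truth_rows.append(
                    {
                        "contig_id": contig_id,
                        "size_class": cls,
                        "circular": circular,
                        "true_length": true_len,
                        "emitted_length": len(seq),
                        "repeat_len": k,
                        "coverage": coverage,
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "contig_id", "size_class", "circular",
            "true_length", "emitted_length", "repeat_len", "coverage",
        ],
    )
    return records, truth


def spike_community(
    community: ParticleCommunity,
    reads: int,
    seed: int = 0,
    spike_feature_id: str = "Q33",
) -> CountMatrix:
    """Shotgun-sample one spiked sample as a single-row CountMatrix.

    Read counts are multinomial with per-feature probability proportional to
    particle_count x genome_length; the spike enters as one extra feature so
    its expected read fraction is S*L_s / (S*L_s + sum N_i*L_i).
    """
    if reads < 1:
        raise ValueError("reads must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.append(
        community.particle_counts * community.genome_lengths,
        community.spike_titre * community.spike_genome_length,
    )
    total = weights.sum()
    if total == 0:
        raise ValueError("community has zero total nucleic acid; cannot sample reads")
    counts = rng.multinomial(reads, weights / total)
    n_endo = len(community.particle_counts)
    feature_ids = [f"f{j}" for j in range(n_endo)] + [spike_feature_id]
    lengths = np.append(
        community.genome_lengths, community.spike_genome_length
    ).astype(np.int64)
    return CountMatrix(
        sample_ids=["sample0"],
        feature_ids=feature_ids,
        counts=counts[None, :],
        feature_lengths=lengths,
        spike_feature_id=spike_feature_id,
    )


def generate_marker_fractions(
    bacterial_dna_fraction: float, marker: MarkerModel
) -> float:
    """Expected marker read fraction for a given bacterial-DNA fraction.

    Exact inverse of :func:`phageome.contamination.estimate_bacterial_fraction`
    below the cap: returns fraction x (copies x marker_length / genome_size).
    """
    if not 0.0 <= bacterial_dna_fraction <= 1.0:
        raise ValueError("bacterial_dna_fraction must be in [0, 1]")
    return bacterial_dna_fraction * marker.marker_fraction_of_genome
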