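"""Shared data model and on-disk formats for the phageome pipeline.

All pipeline artifacts are plain text: FASTA for contigs and tab-separated
UTF-8 tables (mandatory header row) for counts, feature lengths and sample
metadata. Count matrices are stored features-as-rows, the convention of
read-mapping count tables, but held in memory addressed ``(sample, feature)``.
Per-contig mean fold-coverage travels as a ``cov=<x>`` token on the FASTA
header, mirroring common assembler output; circularity as ``circular=<0|1>``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ContigRecord",
    "CountMatrix",
    "SampleMetadata",
    "read_fasta",
    "write_fasta",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "write_manifest",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass
class ContigRecord:
    """One assembled contig: sequence, mean fold-coverage and circularity."""

    contig_id: str
    sequence: str
    coverage: float = 0.0
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValueError("contig_id must be non-empty")
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        bad = next(
            (i for i, c in enumerate(self.sequence) if c not in _VALID_BASES), None
        )
        if bad is not None:
            raise ValueError(
                f"contig {self.contig_id!r}: invalid character "
                f"{self.sequence[bad]!r} at position {bad}"
            )
        if self.coverage < 0:
            raise ValueError(f"contig {self.contig_id!r}: negative coverage")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def with_sequence(self, sequence: str, *, circular: Optional[bool] = None) -> "ContigRecord":
        return replace(
            self,
            sequence=sequence,
            circular=self.circular if circular is None else circular,
        )


@dataclass
class SampleMetadata:
    """Experimental factors attached to one sequenced sample.

    ``treatment`` encodes the manipulated condition of the experiment at hand
    (storage mode/time, freeze-thaw cycle index, ...); ``operator`` is kept as
    a separate optional factor so operator-reproducibility designs can be
    analysed jointly with donor and treatment.
    """

    sample_id: str
    donor: str
    treatment: str
    timepoint: str = "0"
    operator: Optional[str] = None
    spike_titre: Optional[float] = None

    def __post_init__(self) -> None:
        if self.spike_titre is not None and self.spike_titre < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative spike_titre")


@dataclass
class CountMatrix:
    """Samples x features non-negative read counts with feature genome lengths.

    ``counts[i, j]`` is the read count of sample ``sample_ids[i]`` for feature
    ``feature_ids[j]``. ``spike_feature_id`` designates the exogenous internal
    standard, when present.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray
    feature_lengths: np.ndarray
    spike_feature_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.feature_lengths = np.asarray(self.feature_lengths)
        n_s, n_f = len(self.sample_ids), len(self.feature_ids)
        if self.counts.shape != (n_s, n_f):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{n_s} samples x {n_f} features"
            )
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != n_f:
            raise ValueError("duplicate feature ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if self.feature_lengths.shape != (n_f,):
            raise ValueError("feature_lengths must align with feature_ids")
        if (self.feature_lengths <= 0).any():
            raise ValueError("feature_lengths must be positive")
        if self.spike_feature_id is not None and self.spike_feature_id not in self.feature_ids:
            raise ValueError(f"spike feature {self.spike_feature_id!r} not in feature_ids")

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Counts as a features-as-rows DataFrame (on-disk orientation)."""
        return pd.DataFrame(
            self.counts.T, index=self.feature_ids, columns=self.sample_ids
        )


# ---------------------------------------------------------------------------
# FASTA


def _parse_header_tokens(description: str) -> dict[str, str]:
    tokens = {}
    for tok in description.split()[1:]:
        if "=" in tok:
            key, _, val = tok.partition("=")
            tokens[key] = val
    return tokens


def read_fasta(path: str | Path) -> list[ContigRecord]:
    """Read contigs from FASTA.

    Coverage is parsed from a ``cov=<x>`` header token when present (else 0);
    circularity from ``circular=<0|1>`` (else False). Duplicate IDs and
    non-{A,C,G,T,N} characters are hard errors.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        tokens = _parse_header_tokens(rec.description)
        coverage = float(tokens.get("cov", 0.0))
        circular = tokens.get("circular", "0") in ("1", "true", "True")
        records.append(
            ContigRecord(
                contig_id=rec.id,
                sequence=str(rec.seq).upper(),
                coverage=coverage,
                circular=circular,
            )
        )
    return records


def write_fasta(records: Iterable[ContigRecord], path: str | Path) -> None:
    """Write contigs as 60-column wrapped FASTA with cov=/circular= tokens."""
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.contig_id,
            description=f"cov={r.coverage!r} circular={int(r.circular)}",
        )
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Count tables


def read_count_table(
    counts_path: str | Path,
    lengths_path: str | Path,
    spike_feature_id: Optional[str] = None,
) -> CountMatrix:
    """Read a features-as-rows TSV count table plus its feature-length sidecar.

    The sidecar is a two-column TSV ``feature_id<TAB>length``. Missing lengths
    for any counted feature are an error, as are negative or non-integer cells
    (reported with their (feature, sample) coordinates).
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r} in {counts_path}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        frac = np.mod(values.astype(float), 1) != 0
        if frac.any():
            i, j = np.argwhere(frac)[0]
            raise ValueError(
                f"non-integer count at feature {df.index[i]!r}, "
                f"sample {df.columns[j]!r} in {counts_path}"
            )
        values = values.astype(np.int64)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r} in {counts_path}"
        )
    lengths_df = pd.read_csv(lengths_path, sep="\t", index_col=0)
    lengths = lengths_df.iloc[:, 0]
    missing = [f for f in df.index if f not in lengths.index]
    if missing:
        raise ValueError(f"missing feature lengths for {missing} in {lengths_path}")
    feature_lengths = lengths.loc[df.index].to_numpy(dtype=np.int64)
    return CountMatrix(
        sample_ids=list(df.columns.astype(str)),
        feature_ids=list(df.index.astype(str)),
        counts=values.T,
        feature_lengths=feature_lengths,
        spike_feature_id=spike_feature_id,
    )


def write_count_table(
    matrix: CountMatrix, counts_path: str | Path, lengths_path: str | Path
) -> None:
    matrix.to_frame().to_csv(counts_path, sep="\t", index_label="feature_id")
    pd.DataFrame(
        {"length": matrix.feature_lengths}, index=matrix.feature_ids
    ).to_csv(lengths_path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# Sample metadata


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "donor", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        titre = getattr(row, "spike_titre", None)
        titre_val = None
        if titre is not None and not pd.isna(titre) and str(titre) != "":
            titre_val = float(titre)
        operator = getattr(row, "operator", None)
        if operator is not None and pd.isna(operator):
            operator = None
        out.append(
            SampleMetadata(
                sample_id=str(row.sample_id),
                donor=str(row.donor),
                treatment=str(row.treatment),
                timepoint=str(getattr(row, "timepoint", "0")),
                operator=None if operator is None else str(operator),
                spike_titre=titre_val,
            )
        )
    return out


def write_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "donor": [m.donor for m in metadata],
            "treatment": [m.treatment for m in metadata],
            "timepoint": [m.timepoint for m in metadata],
            "operator": ["" if m.operator is None else m.operator for m in metadata],
            "spike_titre": [
                "" if m.spike_titre is None else repr(m.spike_titre) for m in metadata
            ],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run manifests


def write_manifest(
    path: str | Path,
    command: str,
    parameters: Mapping[str, object],
    input_paths: Sequence[str | Path] = (),
    seed: Optional[int] = None,
) -> None:
    """Write a machine-readable record of one pipeline invocation."""

    def checksum(p: str | Path) -> str:
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        return h.hexdigest()

    manifest = {
        "command": command,
        "seed": seed,
        "parameters": dict(parameters),
        "inputs": {str(p): checksum(p) for p in input_paths},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
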