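"""Core in-memory containers shared across the pipeline.

The protein-abundance matrix is the entry point of every analysis: a wide
protein x sample table of raw LC-MS/MS intensities with missing cells, paired
with per-sample metadata (condition, experiment batch, replicate index).
Gene lists and ortholog maps are the thin annotation containers consumed by
the filtering and overlap stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

REQUIRED_METADATA_COLUMNS = ("condition", "experiment", "replicate")


@dataclass
class AbundanceMatrix:
    """Protein x sample raw-intensity table with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample id.
        Cells are raw (linear-scale) intensities; ``NaN`` means missing.
        Zero is not a measurable intensity on the log scale and is mapped
        to missing by the readers before this container is built.
    metadata
        DataFrame indexed by sample id with columns ``condition``,
        ``experiment`` and ``replicate``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate protein ids: {dupes}")
        cols = self.values.columns
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dupes}")
        missing_meta = [s for s in cols if s not in self.metadata.index]
        if missing_meta:
            raise ValidationError(
                f"samples without metadata: {missing_meta}"
            )
        for col in REQUIRED_METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")
        vals = self.values.to_numpy(dtype=float)
        bad = np.where(np.nan_to_num(vals, nan=1.0) <= 0)
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                "non-positive intensity for protein "
                f"{idx[i]!r} in sample {cols[j]!r}: {vals[i, j]!r} "
                "(zeros must be encoded as missing)"
            )

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the intensity is missing."""
        return self.values.isna()

    def samples_for(self, condition: str | None = None,
                    experiment: str | None = None) -> list[str]:
        """Sample ids matching the given condition and/or experiment label."""
        meta = self.metadata.loc[list(self.values.columns)]
        keep = pd.Series(True, index=meta.index)
        if condition is not None:
            keep &= meta["condition"] == condition
        if experiment is not None:
            keep &= meta["experiment"] == experiment
        return list(meta.index[keep])

    def subset_samples(self, samples: list[str]) -> "AbundanceMatrix":
        absent = [s for s in samples if s not in self.values.columns]
        if absent:
            raise ValidationError(f"unknown samples requested: {absent}")
        return AbundanceMatrix(
            values=self.values[samples].copy(),
            metadata=self.metadata.loc[samples].copy(),
        )

    def subset_experiment(self, experiment: str) -> "AbundanceMatrix":
        samples = self.samples_for(experiment=experiment)
        if not samples:
            raise ValidationError(f"no samples for experiment {experiment!r}")
        return self.subset_samples(samples)


@dataclass
class GeneList:
    """A named set of gene/protein identifiers with optional per-member scores.

    Scores, when present, cover a subset of the members (e.g. a confidence
    tier per disease gene); membership itself never requires a score.
    """

    name: str
    members: tuple[str, ...]
    scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            seen: set[str] = set()
            dupes = sorted({m for m in self.members if m in seen or seen.add(m)})
            raise ValidationError(
                f"gene list {self.name!r} has duplicate members: {dupes}"
            )
        if self.scores is not None:
            extra = sorted(set(self.scores) - set(self.members))
            if extra:
                raise ValidationError(
                    f"gene list {self.name!r} has scores for non-members: {extra}"
                )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.as_set

    @property
    def as_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def score_of(self, member: str) -> float | None:
        if self.scores is None:
            return None
        return self.scores.get(member)


@dataclass
class OrthologMap:
    """One-to-many ortholog prediction records with integer confidence scores.

    ``records`` has columns ``source_id``, ``target_id``, ``score``; scores
    live on the 0-15 integrated-confidence scale and (source, target) pairs
    are unique.
    """

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ("source_id", "target_id", "score")
        for col in required:
            if col not in self.records.columns:
                raise ValidationError(f"ortholog map lacks column {col!r}")
        scores = self.records["score"].to_numpy()
        if ((scores < 0) | (scores > 15)).any():
            bad = self.records.loc[(scores < 0) | (scores > 15)]
            raise ValidationError(
                f"ortholog scores outside [0, 15]: {bad.iloc[0].to_dict()}"
            )
        dup = self.records.duplicated(subset=["source_id", "target_id"])
        if dup.any():
            pair = self.records.loc[dup].iloc[0]
            raise ValidationError(
                "duplicate ortholog pair "
                f"({pair['source_id']!r}, {pair['target_id']!r})"
            )

    def __len__(self) -> int:
        return len(self.records)
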