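"""Core data structures shared by every pipeline stage.

An :class:`AbundanceMatrix` is the common currency: a dense features x samples
grid of non-negative abundances (``NaN`` encodes a missing / undetected cell)
together with per-sample design metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRAINS = ("WT", "MUT")
MODALITIES = ("metabolomics", "proteomics")
SCALES = ("raw", "normalized", "log2", "scaled")


@dataclass(frozen=True)
class SampleMeta:
    """Design metadata for one sample column."""

    sample_id: str
    strain: str
    phase: str
    replicate: int

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(
                f"strain must be one of {STRAINS}, got {self.strain!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def group(self) -> tuple[str, str]:
        return (self.strain, self.phase)


def _validate_samples(samples: Sequence[SampleMeta]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {dup}")
    triples = [(s.strain, s.phase, s.replicate) for s in samples]
    if len(set(triples)) != len(triples):
        dup = sorted({t for t in triples if triples.count(t) > 1})
        raise ValueError(f"duplicate (strain, phase, replicate) triple(s): {dup}")


@dataclass
class AbundanceMatrix:
    """Features x samples abundance grid with sample metadata.

    Parameters
    ----------
    data
        DataFrame indexed by feature id, one column per sample id, float
        dtype.  ``NaN`` marks a missing (undetected) cell.
    samples
        One :class:`SampleMeta` per column, in column order.
    modality
        ``"metabolomics"`` or ``"proteomics"``.
    scale
        One of ``raw | normalized | log2 | scaled``.
    standard_id
        Feature id of a retained internal-standard row, if any.  The row is
        kept for provenance but excluded from :meth:`analysis_features`.
    """

    data: pd.DataFrame
    samples: list[SampleMeta]
    modality: str
    scale: str = "raw"
    standard_id: str | None = None
    #: cumulative per-sample divisor applied by normalisation steps; lets a
    #: later step recover raw per-sample quantities (e.g. the raw internal-
    #: standard signal) so normalisations commute exactly
    norm_factors: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dup = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicate feature id(s): {dup}")
        _validate_samples(self.samples)
        if list(self.data.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("data columns do not match sample metadata order")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("abundance values must be finite or missing")
        if self.scale in ("raw", "normalized") and np.nanmin(vals, initial=0.0) < 0:
            raise ValueError(f"negative abundance on {self.scale} scale")
        self.data = self.data.astype(float)

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def analysis_features(self) -> list[str]:
        """Feature ids excluding the internal-standard row."""
        return [f for f in self.data.index if f != self.standard_id]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_by_id(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def strain_columns(self, strain: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.strain == strain]

    def with_data(self, data: pd.DataFrame, **changes) -> "AbundanceMatrix":
        """Copy with replaced values (and optionally other fields)."""
        kwargs = dict(
            samples=list(self.samples),
            modality=self.modality,
            scale=self.scale,
            standard_id=self.standard_id,
            norm_factors=dict(self.norm_factors) if self.norm_factors else None,
        )
        kwargs.update(changes)
        return AbundanceMatrix(data=data.copy(), **kwargs)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        keep = list(sample_ids)
        samples = [s for s in self.samples if s.sample_id in set(keep)]
        return AbundanceMatrix(
            data=self.data.loc[:, [s.sample_id for s in samples]].copy(),
            samples=samples,
            modality=self.modality,
            scale=self.scale,
            standard_id=self.standard_id,
            norm_factors=({k: v for k, v in self.norm_factors.items()
                           if k in {s.sample_id for s in samples}}
                          if self.norm_factors else None),
        )

    def log2(self) -> "AbundanceMatrix":
        """log2-transform a raw/normalized matrix (NaN preserved)."""
        if self.scale not in ("raw", "normalized"):
            raise ValueError(f"cannot log2-transform scale {self.scale!r}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=1.0) <= 0:
            raise ValueError("log2 requires strictly positive abundances")
        return self.with_data(np.log2(self.data), scale="log2")


@dataclass(frozen=True)
class PathwayAnnotation:
    """Set of (feature_id, pathway) pairs; a feature may be in many pathways."""

    entries: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for fid, pw in self.entries:
            if not pw:
                raise ValueError(f"empty pathway label for feature {fid!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PathwayAnnotation":
        return cls(entries=frozenset(pairs))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str | Iterable[str]]) -> "PathwayAnnotation":
        pairs = []
        for fid, pw in mapping.items():
            if isinstance(pw, str):
                pairs.append((fid, pw))
            else:
                pairs.extend((fid, p) for p in pw)
        return cls.from_pairs(pairs)

    def pathways_of(self, feature_id: str) -> set[str]:
        return {pw for fid, pw in self.entries if fid == feature_id}

    def features_in(self, pathway: str) -> set[str]:
        return {fid for fid, pw in self.entries if pw == pathway}

    @property
    def pathways(self) -> set[str]:
        return {pw for _, pw in self.entries}

    @property
    def features(self) -> set[str]:
        return {fid for fid, _ in self.entries}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.entries)
        return pd.DataFrame(rows, columns=["feature_id", "pathway"])
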