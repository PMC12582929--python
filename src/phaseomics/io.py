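"""Readers, writers and per-sample normalisers for abundance tables.

File dialects
-------------
* abundance matrix: wide delimited text, first column the feature id, one
  column per sample id (must all appear in the metadata table);
* sample metadata: columns ``sample_id, strain, phase, replicate``;
* pathway annotations: two columns ``feature_id, pathway``;
* MaxQuant ``proteinGroups.txt``: tab-delimited with ``Protein IDs``,
  ``Reverse``, ``Potential contaminant`` and ``LFQ intensity <sample>``
  columns.

Delimiter is auto-detected from the extension (``.tsv`` -> tab, ``.csv`` ->
comma) and can be overridden with ``sep=``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import AbundanceMatrix, PathwayAnnotation, SampleMeta

_NA_STRINGS = ["", "NA", "NaN", "nan", "N/A"]


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_sample_metadata(path: str | Path, sep: str | None = None) -> list[SampleMeta]:
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    required = {"sample_id", "strain", "phase", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing column(s): {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            strain=str(r.strain),
            phase=str(r.phase),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]


def write_sample_metadata(samples: Sequence[SampleMeta], path: str | Path,
                          sep: str | None = None) -> None:
    pd.DataFrame(
        [(s.sample_id, s.strain, s.phase, s.replicate) for s in samples],
        columns=["sample_id", "strain", "phase", "replicate"],
    ).to_csv(path, sep=_sep_for(path, sep), index=False)


def read_abundance_table(
    path: str | Path,
    modality: str,
    meta_path: str | Path,
    sep: str | None = None,
    zero_as_missing: bool | None = None,
) -> AbundanceMatrix:
    """Read a wide abundance table against a sample-metadata table.

    Blank/NA cells become missing.  ``zero_as_missing`` defaults to True for
    proteomics (the LFQ-intensity convention, where 0 means not quantified)
    and False for metabolomics.
    """
    if zero_as_missing is None:
        zero_as_missing = modality == "proteomics"
    meta = read_sample_metadata(meta_path)
    by_id = {s.sample_id: s for s in meta}

    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0,
                     na_values=_NA_STRINGS, keep_default_na=False,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate feature id(s): {dup}")
    for col in df.columns:
        if col not in by_id:
            raise ValueError(f"unknown sample {col}")
    vals = df.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("negative abundance value in table")
    if zero_as_missing:
        df = df.mask(df == 0)
    samples = [by_id[c] for c in df.columns]
    return AbundanceMatrix(data=df, samples=samples, modality=modality, scale="raw")


def write_abundance_table(m: AbundanceMatrix, path: str | Path,
                          sep: str | None = None) -> None:
    df = m.data.copy()
    df.index.name = "feature_id"
    # repr round-trips float64 exactly
    df.to_csv(path, sep=_sep_for(path, sep),
              float_format=lambda v: repr(float(v)))


def normalize_internal_standard(m: AbundanceMatrix, standard_id: str) -> AbundanceMatrix:
    """Divide each sample column by its internal-standard value.

    The standard row is retained (all 1.0 after division) and flagged via
    ``standard_id`` so downstream statistics skip it.
    """
    if standard_id not in m.data.index:
        raise ValueError(f"internal standard {standard_id!r} not in matrix")
    factors = m.norm_factors or {}
    # divide by the RAW standard signal (current value x prior divisors) so
    # that this step commutes exactly with other per-sample divisions
    raw_is = {}
    for s in m.samples:
        v = m.data.at[standard_id, s.sample_id]
        if pd.isna(v) or v <= 0:
            what = "zero" if v == 0 else "missing or non-positive"
            raise ValueError(f"internal standard {what} in {s.sample_id}")
        raw_is[s.sample_id] = float(v) * factors.get(s.sample_id, 1.0)
    divisor = pd.Series(raw_is)
    out = m.data.div(divisor, axis=1)
    new_factors = {s.sample_id: factors.get(s.sample_id, 1.0) * raw_is[s.sample_id]
                   for s in m.samples}
    return m.with_data(out, scale="normalized", standard_id=standard_id,
                       norm_factors=new_factors)


def normalize_wet_weight(m: AbundanceMatrix, weights: Mapping[str, float]) -> AbundanceMatrix:
    """Divide each sample column by its cell-pellet wet weight (grams)."""
    for s in m.samples:
        if s.sample_id not in weights:
            raise ValueError(f"missing wet weight for sample {s.sample_id}")
        w = weights[s.sample_id]
        if not np.isfinite(w) or w <= 0:
            raise ValueError(f"non-positive wet weight for sample {s.sample_id}: {w}")
    factors = m.norm_factors or {}
    divisor = pd.Series({s.sample_id: float(weights[s.sample_id]) for s in m.samples})
    new_factors = {s.sample_id: factors.get(s.sample_id, 1.0) * divisor[s.sample_id]
                   for s in m.samples}
    return m.with_data(m.data.div(divisor, axis=1), scale="normalized",
                       norm_factors=new_factors)


def read_maxquant_protein_groups(path: str | Path, meta_path: str | Path) -> AbundanceMatrix:
    """Parse a MaxQuant proteinGroups-style table into a proteomics matrix.

    Reverse hits and potential contaminants are dropped; LFQ intensity 0 is
    recorded as missing.
    """
    meta = read_sample_metadata(meta_path)
    df = pd.read_csv(path, sep="\t", na_values=_NA_STRINGS,
                     keep_default_na=False, float_precision="round_trip")
    if "Protein IDs" not in df.columns:
        raise ValueError("proteinGroups file lacks a 'Protein IDs' column")
    for flag in ("Reverse", "Potential contaminant"):
        if flag in df.columns:
            df = df[df[flag].fillna("") != "+"]
    lfq_cols = {}
    for s in meta:
        col = f"LFQ intensity {s.sample_id}"
        if col in df.columns:
            lfq_cols[s.sample_id] = col
    if not lfq_cols:
        raise ValueError("no LFQ intensity columns match the sample metadata")
    samples = [s for s in meta if s.sample_id in lfq_cols]
    wide = df.set_index("Protein IDs")[[lfq_cols[s.sample_id] for s in samples]]
    wide.columns = [s.sample_id for s in samples]
    wide = wide.astype(float).mask(lambda d: d == 0)
    wide.index = wide.index.astype(str)
    if wide.index.has_duplicates:
        dup = sorted(wide.index[wide.index.duplicated()].unique())
        raise ValueError(f"duplicate protein id(s): {dup}")
    return AbundanceMatrix(data=wide, samples=samples, modality="proteomics", scale="raw")


def read_pathway_annotations(path: str | Path, sep: str | None = None) -> PathwayAnnotation:
    df = pd.read_csv(path, sep=_sep_for(path, sep), na_values=_NA_STRINGS,
                     keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("pathway table needs two columns (feature_id, pathway)")
    pairs = []
    for fid, pw in df.iloc[:, :2].itertuples(index=False):
        fid = str(fid)
        if pd.isna(pw) or not str(pw).strip():
            raise ValueError(f"empty pathway label for feature {fid!r}")
        pairs.append((fid, str(pw)))
    return PathwayAnnotation.from_pairs(pairs)


def write_pathway_annotations(ann: PathwayAnnotation, path: str | Path,
                              sep: str | None = None) -> None:
    ann.to_frame().to_csv(path, sep=_sep_for(path, sep), index=False)
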