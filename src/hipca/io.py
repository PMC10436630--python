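"""Reading and writing abundance tables, metadata, and fitted models.

Abundance tables follow the MetaPhlAn2 convention: taxa in rows (full
``k__...|p__...|...|s__...`` lineage strings in the first column), one column
per sample, values on the percent scale. In memory the table is transposed to
samples x species and carried as an :class:`AbundanceTable`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

MODEL_FORMAT_VERSION = 1

VALID_LABELS = frozenset({"healthy", "unhealthy"})

_RANK_PREFIX = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
    "strain": "t__",
}


@dataclass
class AbundanceTable:
    """Samples x species relative-abundance table with optional metadata.

    Attributes
    ----------
    data : pandas.DataFrame
        Samples in rows, species in columns, percent-scale relative
        abundances. Non-negative and finite.
    metadata : pandas.DataFrame or None
        Indexed by sample id with columns ``label`` (healthy/unhealthy) and
        ``phenotype``.
    """

    data: pd.DataFrame
    metadata: Optional[pd.DataFrame] = field(default=None)

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            raise ValueError("abundance table contains NaN or infinite values")
        if (values < 0).any():
            raise ValueError("abundance table contains negative values")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species ids: {dupes}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    def all_zero_species(self) -> list[str]:
        """Species with zero abundance in every sample (allowed, flagged)."""
        mask = (self.data.to_numpy() == 0).all(axis=0)
        return [s for s, m in zip(self.data.columns, mask) if m]

    def subset(self, label: str) -> "AbundanceTable":
        """Samples carrying the given health label (metadata required)."""
        if self.metadata is None:
            raise ValueError("table has no metadata; call attach_metadata first")
        ids = self.metadata.index[self.metadata["label"] == label]
        return AbundanceTable(self.data.loc[ids], self.metadata.loc[ids])


def _lineage_rank(lineage: str) -> Optional[str]:
    """Rank of the deepest segment in a MetaPhlAn lineage, or None."""
    last = lineage.split("|")[-1]
    for rank, prefix in _RANK_PREFIX.items():
        if last.startswith(prefix):
            return rank
    return None


def read_metaphlan_table(path, level: Optional[str] = "species") -> AbundanceTable:
    """Read a MetaPhlAn2-style TSV (taxa rows x sample columns).

    Parameters
    ----------
    path : path-like
        TSV whose first column holds taxon lineage strings.
    level : str or None
        Taxonomic rank to retain. For ``"species"`` a row is kept when its
        deepest lineage segment is an ``s__`` token (so no ``t__`` strain
        token is present). ``None`` keeps every row verbatim.

    Notes
    -----
    Sample order and species order follow the file; abundances are parsed
    exactly as printed, with no renormalization after rank filtering.
    """
    path = Path(path)
    if level is not None and level not in _RANK_PREFIX:
        raise ValueError(f"unknown taxonomic level {level!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon ids in {path}: {dupes}")
    if level is not None:
        keep = [t for t in raw.index if _lineage_rank(t) == level]
        raw = raw.loc[keep]
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        try:
            # python float() is correctly rounded, so written values parse
            # back bit-exactly
            numeric[col] = raw[col].astype(float)
        except ValueError:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = raw.index[coerced.isna()][0]
            raise ValueError(
                f"non-numeric cell at row {bad!r}, column {col!r}"
            ) from None
    return AbundanceTable(numeric.T)


def write_table(table: AbundanceTable, path) -> None:
    """Write in MetaPhlAn orientation (taxa rows x sample columns)."""
    # default formatting emits the shortest round-trip repr of each float
    out = table.data.T
    out.index.name = "#clade_name"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "label", "phenotype"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    meta = meta.set_index("sample_id")
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    bad = sorted(set(meta["label"]) - VALID_LABELS)
    if bad:
        raise ValueError(
            f"unknown label value(s) {bad}; expected one of {sorted(VALID_LABELS)}"
        )
    return meta


def attach_metadata(table: AbundanceTable, path) -> AbundanceTable:
    """Attach a sample-metadata TSV (columns sample_id, label, phenotype).

    Every sample in the table must appear in the metadata; metadata rows for
    unknown samples are ignored with a warning.
    """
    meta = read_metadata(path)
    table_ids = set(table.sample_ids)
    absent = [s for s in table.sample_ids if s not in meta.index]
    if absent:
        raise ValueError(f"samples missing from metadata: {absent}")
    extra = [s for s in meta.index if s not in table_ids]
    if extra:
        warnings.warn(f"metadata rows for unknown samples ignored: {extra}")
    return AbundanceTable(table.data, meta.loc[table.sample_ids])


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# -- model serialization -----------------------------------------------------
#
# A single versioned JSON document. Floats are emitted with Python's
# shortest-round-trip repr, so write -> read reproduces every matrix and
# scalar exactly.


def _arr(a) -> Optional[list]:
    return None if a is None else np.asarray(a, dtype=float).tolist()


def write_model(results, path) -> None:
    """Serialize a fitted :class:`~hipca.monitor.HiPCAResults` to JSON."""
    if results.tau2 is None:
        raise ValueError("model is unfitted: control limits have not been computed")
    doc = {
        "format": "hipca-model",
        "version": MODEL_FORMAT_VERSION,
        "features": list(results.features),
        "sigma": results.transform.sigma,
        "mu": _arr(results.transform.mu),
        "sd": _arr(results.transform.sd),
        "dropped_features": list(results.transform.dropped),
        "P": _arr(results.P),
        "eigvals": _arr(results.eigvals),
        "eigvals_res": _arr(results.eigvals_res),
        "d": int(results.d),
        "pve": results.pve,
        "confidence": results.confidence,
        "tau2": results.tau2,
        "delta2": results.delta2,
        "zeta2": results.zeta2,
        "n_train": int(results.n_train),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_model(path):
    """Load a model written by :func:`write_model`."""
    from .monitor import HiPCAResults
    from .preprocess import TransformParams

    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    if doc.get("format") != "hipca-model":
        raise ValueError(f"{path} is not a hipca model file")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {doc.get('version')} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    features = list(doc["features"])
    transform = TransformParams(
        sigma=float(doc["sigma"]),
        mu=np.asarray(doc["mu"], dtype=float),
        sd=np.asarray(doc["sd"], dtype=float),
        features=features,
        dropped=list(doc.get("dropped_features", [])),
    )
    return HiPCAResults(
        P=np.asarray(doc["P"], dtype=float),
        eigvals=np.asarray(doc["eigvals"], dtype=float),
        eigvals_res=np.asarray(doc["eigvals_res"], dtype=float),
        d=int(doc["d"]),
        features=features,
        transform=transform,
        pve=doc["pve"],
        confidence=float(doc["confidence"]),
        tau2=float(doc["tau2"]),
        delta2=None if doc["delta2"] is None else float(doc["delta2"]),
        zeta2=None if doc["zeta2"] is None else float(doc["zeta2"]),
        n_train=int(doc["n_train"]),
    )
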