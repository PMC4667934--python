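"""Shared data model and delimited-text I/O.

All inputs and outputs are delimited text (TSV by default, comma accepted):
beta-level 450K-style methylation matrices, probe manifests, clinical tables,
TF-binding tables and expression matrices.  IDAT-level parsing and
normalization are out of scope — the pipeline starts from beta values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Tokens treated as missing values in every reader.
MISSING_SENTINELS = ("", "NA", "NaN", "null")

#: Closed vocabulary for gene-region annotation.  Anything else maps to "other".
REGIONS = ("TSS200", "Body", "other")

#: Closed vocabulary for CpG-island relation.
CGI_RELATIONS = ("island", "shore", "shelf", "open_sea")


class TableFormatError(ValueError):
    """Raised when an input table violates its declared format."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Probe × sample methylation levels (beta values) in [0, 1].

    ``values`` holds NaN where ``missing_mask`` is True.  ``detection_p``
    optionally carries per-cell detection p-values on the same grid.
    """

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray
    detection_p: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.missing_mask.shape != self.values.shape:
            raise TableFormatError("missing_mask shape differs from values shape")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise TableFormatError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableFormatError("duplicate sample ids")
        obs = self.values[~self.missing_mask]
        if obs.size and (np.nanmin(obs) < 0 or np.nanmax(obs) > 1):
            raise TableFormatError("beta values outside [0, 1]")
        if self.detection_p is not None:
            self.detection_p = np.asarray(self.detection_p, dtype=float)
            if self.detection_p.shape != self.values.shape:
                raise TableFormatError("detection_p shape differs from values shape")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_ids: Iterable[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        idx = []
        for p in probe_ids:
            if p not in lookup:
                raise KeyError(f"probe {p!r} absent from beta matrix")
            idx.append(lookup[p])
        return np.asarray(idx, dtype=int)

    def subset_probes(self, keep: np.ndarray) -> "BetaMatrix":
        """Row subset by boolean mask or integer index, order preserved."""
        return BetaMatrix(
            probe_ids=self.probe_ids[keep],
            sample_ids=self.sample_ids,
            values=self.values[keep],
            missing_mask=self.missing_mask[keep],
            detection_p=None if self.detection_p is None else self.detection_p[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)
        df.index.name = "probe_id"
        return df


@dataclass
class ProbeManifest:
    """Per-probe genomic and gene/region/CGI/enhancer annotation."""

    table: pd.DataFrame  # indexed by probe_id

    REQUIRED = (
        "probe_id", "chromosome", "position", "gene",
        "region", "cgi_relation", "enhancer", "blacklisted",
    )

    def __post_init__(self) -> None:
        df = self.table
        if df.index.name != "probe_id":
            raise TableFormatError("manifest must be indexed by probe_id")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise TableFormatError(f"duplicate probe_id {dup!r} in manifest")
        bad_region = set(df["region"].unique()) - set(REGIONS)
        if bad_region:
            raise TableFormatError(f"unknown region labels {sorted(bad_region)}")
        bad_cgi = set(df["cgi_relation"].unique()) - set(CGI_RELATIONS)
        if bad_cgi:
            raise TableFormatError(f"unknown cgi_relation labels {sorted(bad_cgi)}")
        if (df["position"] <= 0).any():
            raise TableFormatError("positions must be positive")

    @property
    def probe_ids(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ClinicalTable:
    """Per-sample survival and clinical covariates.

    ``time`` is follow-up in days, ``event`` True for death.  age / stage /
    grade / residual may be missing (NaN).
    """

    table: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("sample_id", "time", "event")
    OPTIONAL = ("age", "stage", "grade", "residual")

    def __post_init__(self) -> None:
        df = self.table
        if df.index.name != "sample_id":
            raise TableFormatError("clinical table must be indexed by sample_id")
        if df.index.duplicated().any():
            raise TableFormatError("duplicate sample_id in clinical table")
        if (df["time"] <= 0).any():
            raise TableFormatError("survival times must be > 0")
        if df["event"].isna().any():
            raise TableFormatError("event must be non-missing boolean")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=object)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(sample_ids)])

    def drop_incomplete(self, required: Sequence[str] = OPTIONAL) -> "ClinicalTable":
        """Remove samples with missing values in the given covariates.

        Mirrors the cohort-assembly rule of dropping patients whose clinical
        record is incomplete before model fitting.
        """
        cols = [c for c in required if c in self.table.columns]
        keep = ~self.table[cols].isna().any(axis=1)
        return ClinicalTable(self.table.loc[keep])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TFBindingTable:
    """Long-format transcription-factor → gene binding indicator table."""

    table: pd.DataFrame  # columns tf, gene, bound

    def __post_init__(self) -> None:
        df = self.table
        for col in ("tf", "gene", "bound"):
            if col not in df.columns:
                raise TableFormatError(f"TF table missing column {col!r}")
        if df.duplicated(subset=["tf", "gene"]).any():
            raise TableFormatError("duplicate (tf, gene) pairs")

    def bound_genes(self, tf: str) -> set:
        df = self.table
        return set(df.loc[(df["tf"] == tf) & df["bound"].astype(bool), "gene"])

    @property
    def tfs(self) -> list:
        return sorted(self.table["tf"].unique())


@dataclass
class ExpressionMatrix:
    """Gene × sample expression levels."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise TableFormatError("duplicate gene ids")
        if not np.isfinite(self.values).all():
            raise TableFormatError("expression values must be finite")

    def gene_values(self, gene: str) -> np.ndarray:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} absent from expression matrix")
        return self.values[idx[0]]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_delimited(path, dialect: Optional[str] = None) -> pd.DataFrame:
    sep = dialect if dialect is not None else None  # None -> sniff , or tab
    return pd.read_csv(
        path, sep=sep, engine="python", dtype=str,
        keep_default_na=False, na_values=[],
    )


def read_beta_matrix(path, dialect: Optional[str] = None) -> BetaMatrix:
    """Read a probe × sample beta matrix from delimited text.

    First column holds probe ids, header row holds sample ids.  Sentinel
    tokens (``""``, ``NA``, ``NaN``, ``null``) become missing; any other
    non-numeric or out-of-range cell raises, naming the offending
    probe/sample.
    """
    raw = _read_delimited(path, dialect)
    probe_col = raw.columns[0]
    probes = raw[probe_col].to_numpy(dtype=object)
    if len(set(probes)) != len(probes):
        raise TableFormatError("duplicate probe id in beta matrix")
    samples = np.asarray(raw.columns[1:], dtype=object)
    cells = raw.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(cells.shape, dtype=float)
    mask = np.zeros(cells.shape, dtype=bool)
    for i in range(cells.shape[0]):
        for j in range(cells.shape[1]):
            tok = str(cells[i, j]).strip()
            if tok in MISSING_SENTINELS:
                values[i, j] = np.nan
                mask[i, j] = True
                continue
            try:
                v = float(tok)
            except ValueError:
                raise TableFormatError(
                    f"malformed beta value {tok!r} at probe {probes[i]!r}, "
                    f"sample {samples[j]!r}"
                ) from None
            if not 0.0 <= v <= 1.0:
                raise TableFormatError(
                    f"beta value {v} outside [0,1] at probe {probes[i]!r}, "
                    f"sample {samples[j]!r}"
                )
            values[i, j] = v
    return BetaMatrix(probes, samples, values, mask)


def read_manifest(path, dialect: Optional[str] = None) -> ProbeManifest:
    """Read a probe manifest; unmodelled region labels collapse to "other"."""
    raw = _read_delimited(path, dialect)
    missing = [c for c in ProbeManifest.REQUIRED if c not in raw.columns]
    if missing:
        raise TableFormatError(f"manifest missing required columns: {missing}")
    df = raw.copy()
    df["position"] = df["position"].astype(int)
    df["region"] = [r if r in REGIONS else "other" for r in df["region"]]
    df["cgi_relation"] = [
        c if c in CGI_RELATIONS else "open_sea" for c in df["cgi_relation"]
    ]
    df["enhancer"] = _parse_bool(df["enhancer"])
    df["blacklisted"] = _parse_bool(df["blacklisted"])
    df = df.set_index("probe_id")
    return ProbeManifest(df)


def read_clinical(path, dialect: Optional[str] = None) -> ClinicalTable:
    raw = _read_delimited(path, dialect)
    missing = [c for c in ClinicalTable.REQUIRED if c not in raw.columns]
    if missing:
        raise TableFormatError(f"clinical table missing required columns: {missing}")
    df = raw.replace(list(MISSING_SENTINELS), np.nan).copy()
    df["time"] = df["time"].astype(float)
    df["event"] = _parse_bool(df["event"])
    for col in ("age", "stage", "grade", "residual"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(df.set_index("sample_id"))


def read_tf_binding(path, dialect: Optional[str] = None) -> TFBindingTable:
    raw = _read_delimited(path, dialect)
    df = raw.copy()
    df["bound"] = _parse_bool(df["bound"])
    return TFBindingTable(df)


def read_expression(path, dialect: Optional[str] = None) -> ExpressionMatrix:
    raw = _read_delimited(path, dialect)
    genes = raw.iloc[:, 0].to_numpy(dtype=object)
    samples = np.asarray(raw.columns[1:], dtype=object)
    values = raw.iloc[:, 1:].astype(float).to_numpy()
    return ExpressionMatrix(genes, samples, values)


def _parse_bool(col) -> np.ndarray:
    truthy = {"1", "true", "True", "TRUE", "yes"}
    falsy = {"0", "false", "False", "FALSE", "no"}
    out = np.empty(len(col), dtype=bool)
    for i, tok in enumerate(col):
        t = str(tok).strip()
        if t in truthy:
            out[i] = True
        elif t in falsy:
            out[i] = False
        else:
            raise TableFormatError(f"cannot parse boolean token {tok!r}")
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_table(obj, path, sep: str = "\t") -> None:
    """Serialize a result object or DataFrame as delimited text.

    Round-trip reads return an equal object (reals to 12 significant digits).
    """
    if isinstance(obj, BetaMatrix):
        df = obj.to_frame()
        df.to_csv(path, sep=sep, float_format="%.12g", na_rep="NA")
    elif isinstance(obj, (ProbeManifest, ClinicalTable, TFBindingTable)):
        df = obj.table
        index = not isinstance(obj, TFBindingTable)
        out = df.copy()
        for col in out.columns:
            if out[col].dtype == bool:
                out[col] = out[col].astype(int)
        out.to_csv(path, sep=sep, float_format="%.12g", na_rep="NA", index=index)
    elif isinstance(obj, ExpressionMatrix):
        df = pd.DataFrame(obj.values, index=obj.gene_ids, columns=obj.sample_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep=sep, float_format="%.12g", na_rep="NA")
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep=sep, float_format="%.12g", na_rep="NA",
                   index=obj.index.name is not None)
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
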