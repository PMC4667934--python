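"""Per-gene methylation measures.

Four primary measures on a gene region (promoter TSS200 or gene body):

* region mean — mean beta over the region's probes, per sample;
* IGV (intra-gene variability) — variance of beta over the region's probes,
  per sample.  Adding a constant to every probe of a gene in a sample leaves
  IGV unchanged, which makes it self-calibrating against global methylation
  shifts;
* mean derivative — mean absolute beta difference between genomically
  adjacent probes, per sample (CpG-to-CpG roughness);
* cross-sample variance — mean over probes of each probe's across-sample
  variance, a proxy for intra-tumour heterogeneity when the samples come
  from one tumour.

Variance-type measures require at least 3 probes in the region; means are
computed for any probe count.  Variances use the n−1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, ProbeManifest

MEASURES = ("mean", "igv", "mean_derivative")

#: Minimum probe count for variance-type measures.
MIN_PROBES_VARIANCE = 3


@dataclass
class GeneRegionIndex:
    """Probes of one gene region, ordered by genomic position."""

    gene: str
    region: str
    probe_ids: np.ndarray

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class GeneMeasureMatrix:
    """Gene × sample matrix of one per-gene measure on one region."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    measure: str
    region: str

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene"
        return df

    def gene_values(self, gene: str) -> np.ndarray:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} absent from measure matrix")
        return self.values[idx[0]]

    def subset_genes(self, genes: Sequence[str]) -> "GeneMeasureMatrix":
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [lookup[g] for g in genes]
        return GeneMeasureMatrix(
            self.gene_ids[idx], self.sample_ids, self.values[idx],
            self.measure, self.region,
        )


def build_region_index(
    manifest: ProbeManifest,
    region: str,
    min_probes: int,
) -> List[GeneRegionIndex]:
    """One index per gene with at least ``min_probes`` probes in ``region``.

    Probes are ordered by genomic position.  A gene whose region probes span
    more than one chromosome indicates a malformed manifest and is rejected.
    """
    df = manifest.table
    sub = df[(df["region"] == region) & (df["gene"] != "")]
    out: List[GeneRegionIndex] = []
    for gene, grp in sub.groupby("gene", sort=True):
        if grp["chromosome"].nunique() > 1:
            raise ValueError(f"gene {gene!r} spans multiple chromosomes in manifest")
        if len(grp) < min_probes:
            continue
        ordered = grp.sort_values("position", kind="stable")
        out.append(GeneRegionIndex(
            gene=gene, region=region,
            probe_ids=ordered.index.to_numpy(dtype=object),
        ))
    return out


def _region_values(beta: BetaMatrix, index: GeneRegionIndex) -> np.ndarray:
    rows = beta.probe_index(index.probe_ids)
    vals = beta.values[rows]
    if np.isnan(vals).any():
        raise ValueError(
            f"missing values in gene {index.gene!r}; impute before measuring"
        )
    return vals


def region_mean(beta: BetaMatrix, index: GeneRegionIndex) -> np.ndarray:
    """Arithmetic mean over the region's probes, per sample."""
    return _region_values(beta, index).mean(axis=0)


def region_igv(beta: BetaMatrix, index: GeneRegionIndex, ddof: int = 1) -> np.ndarray:
    """Variance over the region's probes, per sample (denominator n−ddof)."""
    if index.n_probes < MIN_PROBES_VARIANCE:
        raise ValueError(
            f"gene {index.gene!r} has {index.n_probes} probes; "
            f"IGV requires >= {MIN_PROBES_VARIANCE}"
        )
    return _region_values(beta, index).var(axis=0, ddof=ddof)


def mean_derivative(beta: BetaMatrix, index: GeneRegionIndex) -> np.ndarray:
    """Mean |beta(i+1) − beta(i)| over coordinate-adjacent probe pairs."""
    if index.n_probes < 2:
        raise ValueError(f"gene {index.gene!r} needs >= 2 probes for mean derivative")
    vals = _region_values(beta, index)
    return np.abs(np.diff(vals, axis=0)).mean(axis=0)


def cross_sample_variance(
    beta: BetaMatrix,
    index: GeneRegionIndex,
    sample_subset: Optional[Sequence[str]] = None,
    ddof: int = 1,
) -> float:
    """Mean over the region's probes of per-probe across-sample variance."""
    vals = _region_values(beta, index)
    if sample_subset is not None:
        lookup = {s: j for j, s in enumerate(beta.sample_ids)}
        cols = [lookup[s] for s in sample_subset]
        vals = vals[:, cols]
    if vals.shape[1] < 2:
        raise ValueError("cross-sample variance needs >= 2 samples")
    return float(vals.var(axis=1, ddof=ddof).mean())


_MEASURE_FUNCS = {
    "mean": (region_mean, 1),
    "igv": (region_igv, MIN_PROBES_VARIANCE),
    "mean_derivative": (mean_derivative, 2),
}


def measure_matrix(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    measure: str,
    region: str,
    ddof: int = 1,
) -> GeneMeasureMatrix:
    """Apply one per-gene measure to every qualifying gene of a region."""
    if measure not in _MEASURE_FUNCS:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if region not in ("TSS200", "Body"):
        raise ValueError(f"unknown region {region!r}; choose TSS200 or Body")
    func, min_probes = _MEASURE_FUNCS[measure]
    present = set(beta.probe_ids)
    indices = [
        ix for ix in build_region_index(manifest, region, min_probes)
        if all(p in present for p in ix.probe_ids)
    ]
    genes = np.asarray([ix.gene for ix in indices], dtype=object)
    if measure == "igv":
        rows = [func(beta, ix, ddof=ddof) for ix in indices]
    else:
        rows = [func(beta, ix) for ix in indices]
    values = np.vstack(rows) if rows else np.empty((0, beta.n_samples))
    return GeneMeasureMatrix(genes, beta.sample_ids, values, measure, region)
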