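"""Probe filtering, detection-p masking and KNN imputation.

The cleaning sequence for a beta matrix is: drop unusable probes
(blacklisted, sex-chromosomal, unannotated, low coverage), mask cells whose
detection p-value exceeds the threshold, then impute remaining holes by
k-nearest-neighbour averaging over probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from sklearn.impute import KNNImputer

from .core_io import BetaMatrix, ProbeManifest

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY"}


class EmptyMatrixError(ValueError):
    """All probes were removed by filtering."""


@dataclass
class FilterReport:
    """Per-reason accounting of removed probes.

    Each probe is counted once, under the first rule that removed it
    (blacklist → sex chromosome → unannotated → coverage).
    """

    n_input: int
    n_blacklisted: int
    n_sex: int
    n_unannotated: int
    n_low_coverage: int
    n_retained: int
    removed_ids: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (self.n_blacklisted + self.n_sex + self.n_unannotated
                 + self.n_low_coverage + self.n_retained)
        assert total == self.n_input, "filter accounting does not balance"


def filter_probes(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    coverage_min: float = 0.95,
) -> Tuple[BetaMatrix, FilterReport]:
    """Remove blacklisted, sex-chromosome, unannotated and low-coverage probes.

    A probe's coverage is its fraction of non-missing samples; probes below
    ``coverage_min`` are dropped.  Probe order is preserved.
    """
    mtab = manifest.table
    in_manifest = {p: i for i, p in enumerate(mtab.index)}
    removed: Dict[str, List[str]] = {
        "blacklisted": [], "sex": [], "unannotated": [], "low_coverage": []
    }
    keep = np.ones(beta.n_probes, dtype=bool)
    coverage = 1.0 - beta.missing_mask.mean(axis=1)
    for i, probe in enumerate(beta.probe_ids):
        if probe not in in_manifest:
            removed["unannotated"].append(probe)
            keep[i] = False
            continue
        row = mtab.loc[probe]
        if bool(row["blacklisted"]):
            removed["blacklisted"].append(probe)
            keep[i] = False
        elif str(row["chromosome"]) in SEX_CHROMOSOMES:
            removed["sex"].append(probe)
            keep[i] = False
        elif coverage[i] < coverage_min:
            removed["low_coverage"].append(probe)
            keep[i] = False
    if not keep.any():
        raise EmptyMatrixError("empty matrix after filtering")
    report = FilterReport(
        n_input=beta.n_probes,
        n_blacklisted=len(removed["blacklisted"]),
        n_sex=len(removed["sex"]),
        n_unannotated=len(removed["unannotated"]),
        n_low_coverage=len(removed["low_coverage"]),
        n_retained=int(keep.sum()),
        removed_ids=removed,
    )
    return beta.subset_probes(keep), report


def mask_by_detection(beta: BetaMatrix, p_max: float = 0.05) -> BetaMatrix:
    """Mark cells with detection p-value strictly greater than ``p_max`` missing."""
    if beta.detection_p is None:
        warnings.warn("no detection p-values present; mask_by_detection is a no-op")
        return beta
    bad = beta.detection_p > p_max
    values = beta.values.copy()
    values[bad] = np.nan
    return BetaMatrix(
        probe_ids=beta.probe_ids,
        sample_ids=beta.sample_ids,
        values=values,
        missing_mask=beta.missing_mask | bad,
        detection_p=beta.detection_p,
    )


def knn_impute(beta: BetaMatrix, k: int = 5) -> BetaMatrix:
    """Impute missing cells by the mean of the k nearest probes' values.

    Distance between probe rows is Euclidean over jointly observed samples,
    scaled by the number of shared samples (the nan-Euclidean convention of
    methylation-array KNN imputation).  Neighbours contribute unweighted.
    """
    fully_missing = beta.missing_mask.all(axis=1)
    if fully_missing.any():
        bad = beta.probe_ids[fully_missing][0]
        raise ValueError(f"probe {bad!r} has no observed values; cannot impute")
    if beta.n_probes < k + 1:
        raise ValueError(f"need at least k+1={k + 1} probes for k={k} imputation")
    if not beta.missing_mask.any():
        return beta
    X = beta.values.copy()
    X[beta.missing_mask] = np.nan
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    # KNNImputer treats rows as observations: probes are the rows here.
    filled = imputer.fit_transform(X)
    filled = np.clip(filled, 0.0, 1.0)
    return BetaMatrix(
        probe_ids=beta.probe_ids,
        sample_ids=beta.sample_ids,
        values=filled,
        missing_mask=np.zeros_like(beta.missing_mask),
        detection_p=beta.detection_p,
    )


def preprocess(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    coverage_min: float = 0.95,
    detection_pmax: float = 0.05,
    knn_k: int = 5,
) -> Tuple[BetaMatrix, FilterReport]:
    """Full cleaning sequence: filter → detection mask → KNN impute."""
    filtered, report = filter_probes(beta, manifest, coverage_min)
    if filtered.detection_p is not None:
        filtered = mask_by_detection(filtered, detection_pmax)
    if filtered.missing_mask.any():
        filtered = knn_impute(filtered, knn_k)
    return filtered, report
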