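"""Metabolite table QC, normalization, mass matching, and DEC calling.

The LC-MS workflow modelled here starts from an aligned peak table
(compound × sample intensities with m/z and retention time): ions with
high replicate variability (RSD > 30%) are removed, samples are brought
to a common median intensity, putative identities are screened by mass
accuracy (< 10 ppm), and differential compounds (DECs) between high- and
low-glucose cultures are called by a Welch test on log2 intensities at
fold > 4 and p < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import AnalysisConfig, MetaboliteTable, ValidationError


@dataclass
class DECRecord:
    compound_id: str
    log2fc: float  # high over low glucose
    p_value: float  # Welch two-sided on log2 intensities
    reg_class: str  # up | down | unchanged


@dataclass
class RemovalLogEntry:
    compound_id: str
    rsd_percent: float
    reason: str


def rsd_filter(
    table: MetaboliteTable,
    config: Optional[AnalysisConfig] = None,
    qc_samples: Optional[Sequence[str]] = None,
) -> tuple[MetaboliteTable, list[RemovalLogEntry]]:
    """Remove compounds with relative standard deviation above the threshold.

    RSD = 100 * sd / mean. When ``qc_samples`` (a dedicated QC-injection
    column set) is given, RSD is computed across those columns; otherwise
    it is computed within each biological condition and the worst
    (maximum) condition RSD is used, so that genuine between-condition
    differences never count as technical variability. Compounds with a
    zero mean are removed with reason "zero mean". Idempotent.
    """
    config = config or AnalysisConfig()
    if qc_samples is not None:
        groups = {"qc": list(qc_samples)}
    else:
        groups = {c: table.samples_for(c) for c in table.conditions()}
    for name, cols in groups.items():
        if len(cols) < 2:
            raise ValidationError(f"RSD filter needs >= 2 replicates in {name!r}")
    removed: list[RemovalLogEntry] = []
    keep = []
    for cid in table.compound_ids:
        worst = 0.0
        zero_mean = False
        for cols in groups.values():
            vals = table.intensities.loc[cid, cols]
            m = vals.mean()
            if m == 0:
                zero_mean = True
                break
            worst = max(worst, 100.0 * vals.std(ddof=1) / m)
        if zero_mean:
            removed.append(RemovalLogEntry(cid, float("nan"), "zero mean"))
        elif worst > config.rsd_max_percent:
            removed.append(RemovalLogEntry(cid, float(worst), "RSD above threshold"))
        else:
            keep.append(cid)
    return table.subset(keep), removed


def normalize_median(table: MetaboliteTable) -> tuple[MetaboliteTable, pd.Series]:
    """Scale each sample so its median intensity equals the grand median.

    A light-weight stand-in for injection-order signal correction; it
    removes per-sample global intensity drift while leaving relative
    compound patterns untouched. Returns the table and the per-sample
    scaling factors applied.
    """
    medians = table.intensities.median(axis=0)
    grand = float(np.median(table.intensities.to_numpy()))
    factors = grand / medians
    normalized = table.intensities.mul(factors, axis=1)
    out = MetaboliteTable(
        intensities=normalized,
        mz=table.mz,
        rt=table.rt,
        sample_meta=table.sample_meta,
        annotation=table.annotation,
    )
    return out, factors


def ppm_match(
    observed_mz: float,
    candidates: Sequence[tuple[str, float]],
    ppm_max: float = 10.0,
) -> list[tuple[str, float]]:
    """Candidate identities within the mass-accuracy window (strict <).

    Returns (id, ppm) pairs with ppm = 1e6*|observed - theoretical|/theoretical,
    sorted by ppm ascending.
    """
    if observed_mz <= 0:
        raise ValidationError("observed m/z must be positive")
    matches = []
    for cid, theoretical in candidates:
        if theoretical <= 0:
            raise ValidationError(f"theoretical mass for {cid!r} must be positive")
        ppm = 1e6 * abs(observed_mz - theoretical) / theoretical
        if ppm < ppm_max:
            matches.append((cid, ppm))
    matches.sort(key=lambda pair: (pair[1], pair[0]))
    return matches


def call_decs(
    table: MetaboliteTable,
    config: Optional[AnalysisConfig] = None,
    low_condition: str = "low",
    high_condition: str = "high",
) -> list[DECRecord]:
    """Differential compounds between high- and low-glucose cultures.

    Welch two-sample t-test on log2 intensities; log2fc is mean high
    minus mean low on the log2 scale. Class "up"/"down" requires
    |fold| > dec_fold and p < dec_p.
    """
    config = config or AnalysisConfig()
    low = table.samples_for(low_condition)
    high = table.samples_for(high_condition)
    if len(low) < 3 or len(high) < 3:
        raise ValidationError(
            f"need >= 3 replicates per condition, got {len(low)} low / {len(high)} high"
        )
    log_low = np.log2(table.intensities[low].to_numpy(dtype=float))
    log_high = np.log2(table.intensities[high].to_numpy(dtype=float))
    lfc = log_high.mean(axis=1) - log_low.mean(axis=1)
    tstat, pvals = stats.ttest_ind(log_high, log_low, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    records = []
    thr = config.log2_dec_fold
    for i, cid in enumerate(table.compound_ids):
        if abs(lfc[i]) > thr and pvals[i] < config.dec_p:
            cls = "up" if lfc[i] > 0 else "down"
        else:
            cls = "unchanged"
        records.append(DECRecord(cid, float(lfc[i]), float(pvals[i]), cls))
    return records


def pca_report(table: MetaboliteTable, n_components: int = 2):
    """Sample PCA on log2 intensities (QC only: scores + variance explained)."""
    from sklearn.decomposition import PCA

    X = np.log2(table.intensities.to_numpy(dtype=float)).T
    X = X - X.mean(axis=0)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return (
        pd.DataFrame(
            scores,
            index=table.intensities.columns,
            columns=[f"PC{i+1}" for i in range(scores.shape[1])],
        ),
        pca.explained_variance_ratio_,
    )
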