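"""Differential expression on the count matrix.

The test is an exact conditional test for negative-binomial counts with a
single common dispersion phi (variance = mu + phi*mu^2). After scaling
counts to a common library size, replicate counts in each group are
summed; under the null the group-A total conditioned on the grand total
follows the NB-convolution conditional law (a beta-binomial with shape
parameters n_A/phi and n_B/phi), which degenerates to the exact binomial
split Binomial(t, n_A/(n_A+n_B)) at phi = 0. Two-sided p-values sum the
probabilities of all outcomes no more probable than the observed one.

Gene-level fold-changes are ratios of mean TPM with a pseudocount; the
"significant" grade uses fold > deg_fold with BH-FDR q < deg_fdr, and a
"moderate" grade (fold > moderate_fold) supports the pathway heatmaps.
Enzymes with several isoforms are additionally tested on their summative
(summed) levels at the looser summative_fold / summative_p thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .types import (
    AnalysisConfig,
    Condition,
    CountMatrix,
    GeneAnnotationTable,
    ValidationError,
)

REG_CLASSES = ("significant_up", "significant_down", "moderate_up", "moderate_down", "unchanged")


@dataclass
class DEGRecord:
    gene_id: str
    condition_a: str
    condition_b: str
    mean_a: float  # mean TPM in A
    mean_b: float  # mean TPM in B
    log2fc: float  # log2((mean_b + pc) / (mean_a + pc))
    p_value: float
    q_value: float
    reg_class: str


@dataclass
class SummativeRecord:
    group_id: str
    n_isoforms: int
    log2fc: float  # on summed abundances
    p_value: float  # on summed counts
    n_significant_isoforms: int
    reg_class: str
    discordant: bool


# -- normalization ----------------------------------------------------------


def compute_tpm(matrix: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: per sample, 1e6 * (c_g/L_g) / sum_j (c_j/L_j)."""
    lengths = np.asarray(matrix.effective_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValidationError("effective lengths must be positive")
    rates = matrix.counts.div(pd.Series(lengths, index=matrix.counts.index), axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has all-zero counts")
    return rates.div(totals, axis=1) * 1e6


def size_factors(matrix: CountMatrix, samples: Sequence[str]) -> pd.Series:
    """Total-count scaling factors: library size / mean library size."""
    libs = matrix.counts[list(samples)].sum(axis=0).astype(float)
    return libs / libs.mean()


# -- dispersion -------------------------------------------------------------


def estimate_dispersion(matrix: CountMatrix, conditions: tuple[str, str]) -> float:
    """Common NB dispersion by method of moments on library-scaled counts.

    Per gene and condition, phi_g = max(0, (s^2 - m)/m^2) from replicate
    mean m and variance s^2; the estimate is the median over (gene,
    condition) cells with m >= 5. Low-mean cells are excluded because
    moment estimates there are dominated by Poisson noise.
    """
    estimates = []
    for label in conditions:
        samples = matrix.samples_for(label)
        if len(samples) < 2:
            raise ValidationError(
                f"condition {label!r} has a single replicate; supply phi explicitly"
            )
        sf = size_factors(matrix, samples)
        scaled = matrix.counts[samples].div(sf, axis=1).to_numpy(dtype=float)
        m = scaled.mean(axis=1)
        s2 = scaled.var(axis=1, ddof=1)
        keep = m >= 5
        phi_g = np.maximum(0.0, (s2[keep] - m[keep]) / m[keep] ** 2)
        estimates.append(phi_g)
    allphi = np.concatenate(estimates)
    if allphi.size == 0:
        return 0.0
    return float(np.median(allphi))


# -- exact test -------------------------------------------------------------


def _conditional_logpmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log P(A-total = x | grand total = t) for x = 0..t under H0."""
    x = np.arange(t + 1)
    if phi == 0.0:
        # Poisson conditioning -> Binomial(t, n_a/(n_a+n_b))
        p = n_a / (n_a + n_b)
        logw = (
            gammaln(t + 1)
            - gammaln(x + 1)
            - gammaln(t - x + 1)
            + x * math.log(p)
            + (t - x) * math.log1p(-p)
        )
        return logw
    r_a = n_a / phi
    r_b = n_b / phi
    logw = (
        gammaln(x + r_a)
        - gammaln(x + 1)
        + gammaln(t - x + r_b)
        - gammaln(t - x + 1)
    )
    return logw - logsumexp(logw)


def nb_exact_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    phi: float,
    size_factors_a: Optional[Sequence[float]] = None,
    size_factors_b: Optional[Sequence[float]] = None,
) -> float:
    """Two-sided exact conditional NB test for two replicate groups.

    Counts are scaled to equal libraries by the size factors, summed per
    group and rounded; the p-value sums conditional probabilities of all
    splits of the total no more probable than the observed split (ties
    included, with a 1e-9 relative guard for floating near-ties).
    """
    if phi < 0:
        raise ValidationError("dispersion phi must be >= 0")
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.size == 0 or counts_b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if size_factors_a is not None:
        counts_a = counts_a / np.asarray(size_factors_a, dtype=float)
    if size_factors_b is not None:
        counts_b = counts_b / np.asarray(size_factors_b, dtype=float)
    a = int(round(counts_a.sum()))
    b = int(round(counts_b.sum()))
    t = a + b
    if t == 0:
        return 1.0
    logw = _conditional_logpmf(t, counts_a.size, counts_b.size, phi)
    log_obs = logw[a]
    # include outcomes with probability <= observed (ties included)
    mask = logw <= log_obs + 1e-9
    if mask.all():
        return 1.0
    return float(min(1.0, np.exp(logsumexp(logw[mask]) - logsumexp(logw))))


def _exact_test_totals(a: int, b: int, n_a: int, n_b: int, phi: float) -> float:
    """Exact test on pre-summed (already library-equalized) group totals."""
    t = a + b
    if t == 0:
        return 1.0
    logw = _conditional_logpmf(t, n_a, n_b, phi)
    mask = logw <= logw[a] + 1e-9
    if mask.all():
        return 1.0
    return float(min(1.0, np.exp(logsumexp(logw[mask]) - logsumexp(logw))))


# -- FDR --------------------------------------------------------------------


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- gene-level calls -------------------------------------------------------


def classify(log2fc: float, p: float, q: float, config: AnalysisConfig) -> str:
    """Tri-state(+sign) regulation grade at the DEG thresholds."""
    if abs(log2fc) > config.log2_deg_fold and q < config.deg_fdr:
        return "significant_up" if log2fc > 0 else "significant_down"
    if abs(log2fc) > config.log2_moderate_fold:
        return "moderate_up" if log2fc > 0 else "moderate_down"
    return "unchanged"


def call_degs(
    matrix: CountMatrix,
    comparison: tuple[str, str],
    config: AnalysisConfig,
    phi: Optional[float] = None,
) -> list[DEGRecord]:
    """Per-gene DEG records for condition B vs condition A.

    ``comparison`` is (A, B); log2fc is B over A on mean TPM with the
    configured pseudocount, so a positive value means higher in B.
    """
    label_a, label_b = comparison
    if label_a == label_b:
        raise ValidationError("cannot compare a condition with itself")
    Condition.from_label(label_a)
    Condition.from_label(label_b)
    matrix.require_conditions([label_a, label_b])
    samples_a = matrix.samples_for(label_a)
    samples_b = matrix.samples_for(label_b)

    if phi is None:
        phi = estimate_dispersion(matrix, (label_a, label_b))

    tpm = compute_tpm(matrix)
    mean_a = tpm[samples_a].mean(axis=1)
    mean_b = tpm[samples_b].mean(axis=1)
    pc = config.pseudocount
    lfc = np.log2((mean_b + pc) / (mean_a + pc))

    all_samples = samples_a + samples_b
    sf = size_factors(matrix, all_samples)
    scaled = matrix.counts[all_samples].div(sf, axis=1)
    tot_a = scaled[samples_a].sum(axis=1).round().astype(np.int64).to_numpy()
    tot_b = scaled[samples_b].sum(axis=1).round().astype(np.int64).to_numpy()

    n_a, n_b = len(samples_a), len(samples_b)
    pvals = np.ones(len(matrix.gene_ids))
    cache: dict[tuple[int, int], float] = {}
    for i, (a, b) in enumerate(zip(tot_a, tot_b)):
        key = (int(a), int(b))
        p = cache.get(key)
        if p is None:
            p = _exact_test_totals(key[0], key[1], n_a, n_b, phi)
            cache[key] = p
        pvals[i] = p
    qvals = bh_fdr(pvals)

    records = []
    for i, gid in enumerate(matrix.gene_ids):
        records.append(
            DEGRecord(
                gene_id=gid,
                condition_a=label_a,
                condition_b=label_b,
                mean_a=float(mean_a.iloc[i]),
                mean_b=float(mean_b.iloc[i]),
                log2fc=float(lfc.iloc[i]),
                p_value=float(pvals[i]),
                q_value=float(qvals[i]),
                reg_class=classify(float(lfc.iloc[i]), float(pvals[i]), float(qvals[i]), config),
            )
        )
    return records


# -- summative (isoform-group) calls ---------------------------------------


def _classify_summative(log2fc: float, p: float, config: AnalysisConfig) -> str:
    if abs(log2fc) > config.log2_summative_fold and p < config.summative_p:
        return "significant_up" if log2fc > 0 else "significant_down"
    if abs(log2fc) > config.log2_moderate_fold:
        return "moderate_up" if log2fc > 0 else "moderate_down"
    return "unchanged"


def summative_call(
    matrix: CountMatrix,
    annotation: GeneAnnotationTable,
    group_key: str,
    comparison: tuple[str, str],
    config: AnalysisConfig,
    phi: Optional[float] = None,
) -> list[SummativeRecord]:
    """Test enzyme groups (isoform groups or EC numbers) on summed levels.

    Counts of member isoforms are summed per sample before testing, and
    the log-ratio is taken on summed mean TPM. The discordance flag marks
    groups whose summative direction opposes the majority direction of
    the individually significant isoforms (the PGK situation).
    """
    groups = annotation.groups(group_key)
    groups = {g: [m for m in members if m in matrix.gene_ids] for g, members in groups.items()}
    groups = {g: m for g, m in groups.items() if m}
    if not groups:
        raise ValidationError(f"no gene carries a {group_key!r} annotation")

    label_a, label_b = comparison
    matrix.require_conditions([label_a, label_b])
    samples_a = matrix.samples_for(label_a)
    samples_b = matrix.samples_for(label_b)
    if phi is None:
        phi = estimate_dispersion(matrix, (label_a, label_b))

    tpm = compute_tpm(matrix)
    all_samples = samples_a + samples_b
    sf = size_factors(matrix, all_samples)
    scaled = matrix.counts[all_samples].div(sf, axis=1)
    pc = config.pseudocount
    n_a, n_b = len(samples_a), len(samples_b)

    # per-isoform significance at the summative thresholds (raw p)
    records = []
    for gid, members in sorted(groups.items()):
        summed_tpm_a = tpm.loc[members, samples_a].to_numpy().sum(axis=0).mean()
        summed_tpm_b = tpm.loc[members, samples_b].to_numpy().sum(axis=0).mean()
        lfc = math.log2((summed_tpm_b + pc) / (summed_tpm_a + pc))
        tot_a = int(round(scaled.loc[members, samples_a].to_numpy().sum()))
        tot_b = int(round(scaled.loc[members, samples_b].to_numpy().sum()))
        p = _exact_test_totals(tot_a, tot_b, n_a, n_b, phi)

        n_sig = 0
        up_sig = 0
        for m in members:
            ma = tpm.loc[m, samples_a].mean()
            mb = tpm.loc[m, samples_b].mean()
            iso_lfc = math.log2((mb + pc) / (ma + pc))
            a_i = int(round(scaled.loc[m, samples_a].sum()))
            b_i = int(round(scaled.loc[m, samples_b].sum()))
            iso_p = _exact_test_totals(a_i, b_i, n_a, n_b, phi)
            if abs(iso_lfc) > config.log2_summative_fold and iso_p < config.summative_p:
                n_sig += 1
                if iso_lfc > 0:
                    up_sig += 1
        reg = _classify_summative(lfc, p, config)
        discordant = False
        if n_sig >= 1 and lfc != 0:
            majority_up = up_sig > n_sig - up_sig
            majority_down = n_sig - up_sig > up_sig
            if (majority_up and lfc < 0) or (majority_down and lfc > 0):
                discordant = True
        records.append(
            SummativeRecord(
                group_id=gid,
                n_isoforms=len(members),
                log2fc=lfc,
                p_value=p,
                n_significant_isoforms=n_sig,
                reg_class=reg,
                discordant=discordant,
            )
        )
    return records
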