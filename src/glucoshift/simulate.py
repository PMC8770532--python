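"""Synthetic data with the statistical structure the analysis assumes.

The transcriptome generator emulates the reciprocal-shift design: 12
samples (LL, HH, L2H, H2L in triplicate), negative-binomial counts
(variance = mu + phi*mu^2), and planted gene classes:

* ``positive_gsr`` / ``negative_gsr`` — expression scales with the
  *target* glucose level (multiplier applied in HH and L2H), the signal
  the GSR pipeline must recover;
* ``shift_only`` — transient response in both shifted conditions (L2H
  and H2L) in the same direction, which lands in the common DEG set but
  is non-monotonic, giving the monotonicity filter something to reject;
* ``l2h_only`` / ``h2l_only`` — responders specific to one shift
  comparison, which pad the per-comparison DEG fractions to realistic
  study levels (~9.4% and ~7.9%) without entering the common set;
* ``null`` — no planted effect.

Planting is deterministic given the seed; the truth table is returned
alongside each table for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    CONDITIONS,
    AnalysisConfig,
    CountMatrix,
    GeneAnnotationTable,
    MetaboliteTable,
    PathwayMap,
    ValidationError,
)

GENE_CLASSES = ("positive_gsr", "negative_gsr", "shift_only", "l2h_only", "h2l_only", "null")


@dataclass
class TranscriptomeSimSpec:
    """Study-scale defaults: 9,277 genes, 4 conditions x 3 replicates.

    ``frac_*`` are planted-class fractions; GSR effects are |log2
    ratios| drawn Normal(gsr_log2_effect, gsr_log2_effect_sd), well
    above the 4-fold DEG threshold in expectation. ``baseline_sdlog``
    sets the log-normal dynamic range of baseline expression (median
    count ~ 100 at the default library size).
    """

    n_genes: int = 9277
    n_replicates: int = 3
    library_size_mean: float = 2_000_000.0
    library_size_cv: float = 0.1
    nb_dispersion: float = 0.1
    frac_positive_gsr: float = 0.015
    frac_negative_gsr: float = 0.015
    gsr_log2_effect: float = 3.0
    gsr_log2_effect_sd: float = 0.5
    frac_shift_only: float = 0.006
    frac_l2h_only: float = 0.058
    frac_h2l_only: float = 0.043
    min_log2_effect: float = 2.0  # planted |effects| exceed the 4-fold DEG cutoff
    baseline_sdlog: float = 1.2
    rng_seed: int = 0

    def validate(self) -> None:
        total = (
            self.frac_positive_gsr
            + self.frac_negative_gsr
            + self.frac_shift_only
            + self.frac_l2h_only
            + self.frac_h2l_only
        )
        if total >= 1:
            raise ValidationError(f"planted fractions sum to {total}, must be < 1")
        for name in ("frac_positive_gsr", "frac_negative_gsr", "frac_shift_only",
                     "frac_l2h_only", "frac_h2l_only"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")


@dataclass
class SimTruth:
    """Ground-truth labels for recovery tests."""

    gene_classes: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    gene_effects: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    pathway_enriched: dict[str, bool] = field(default_factory=dict)
    compound_classes: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    compound_effects: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def genes_of_class(self, *classes: str) -> set[str]:
        return set(self.gene_classes.index[self.gene_classes.isin(classes)])


def _condition_multiplier_log2(cls: str, label: str, effect: float) -> float:
    """Planted log2 shift of the NB mean for one gene class in one condition."""
    target_high = CONDITIONS[label].target_is_high
    if cls == "positive_gsr":
        return effect if target_high else 0.0
    if cls == "negative_gsr":
        return -effect if target_high else 0.0
    if cls == "shift_only":
        return effect if label in ("L2H", "H2L") else 0.0
    if cls == "l2h_only":
        return effect if label == "L2H" else 0.0
    if cls == "h2l_only":
        return effect if label == "H2L" else 0.0
    return 0.0


def simulate_transcriptome(spec: TranscriptomeSimSpec) -> tuple[CountMatrix, SimTruth]:
    """Generate the 12-sample count matrix plus its truth table."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_genes
    gene_ids = [f"g{i:05d}" for i in range(1, n + 1)]

    # deterministic class counts; random placement
    counts_per_class = {
        "positive_gsr": int(round(spec.frac_positive_gsr * n)),
        "negative_gsr": int(round(spec.frac_negative_gsr * n)),
        "shift_only": int(round(spec.frac_shift_only * n)),
        "l2h_only": int(round(spec.frac_l2h_only * n)),
        "h2l_only": int(round(spec.frac_h2l_only * n)),
    }
    order = rng.permutation(n)
    classes = np.full(n, "null", dtype=object)
    pos = 0
    for cls in ("positive_gsr", "negative_gsr", "shift_only", "l2h_only", "h2l_only"):
        k = counts_per_class[cls]
        classes[order[pos : pos + k]] = cls
        pos += k

    effects = np.zeros(n)
    planted = classes != "null"
    # truncated sampling keeps every planted |effect| above the DEG cutoff
    magnitudes = np.abs(rng.normal(spec.gsr_log2_effect, spec.gsr_log2_effect_sd, planted.sum()))
    for _ in range(100):
        low = magnitudes <= spec.min_log2_effect
        if not low.any():
            break
        magnitudes[low] = np.abs(
            rng.normal(spec.gsr_log2_effect, spec.gsr_log2_effect_sd, int(low.sum()))
        )
    signs = np.ones(planted.sum())
    # shift_only / one-shift classes get a random direction; GSR sign is
    # carried by the class itself (positive vs negative correlation)
    cls_planted = classes[planted]
    random_sign = np.isin(cls_planted, ("shift_only", "l2h_only", "h2l_only"))
    signs[random_sign] = rng.choice([-1.0, 1.0], random_sign.sum())
    effects[planted] = magnitudes * signs

    baseline = rng.lognormal(mean=0.0, sigma=spec.baseline_sdlog, size=n)
    rel_expr = baseline / baseline.sum()

    sample_ids, meta_rows = [], []
    for label in ("LL", "HH", "L2H", "H2L"):
        for rep in range(1, spec.n_replicates + 1):
            sample_ids.append(f"{label}_{rep}")
            meta_rows.append((label, rep))
    sample_meta = pd.DataFrame(meta_rows, columns=["condition", "replicate"], index=sample_ids)

    libs = rng.normal(spec.library_size_mean, spec.library_size_cv * spec.library_size_mean,
                      len(sample_ids))
    libs = np.maximum(libs, 0.1 * spec.library_size_mean)

    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    phi = spec.nb_dispersion
    for j, sid in enumerate(sample_ids):
        label = sample_meta.loc[sid, "condition"]
        log2_mult = np.array(
            [_condition_multiplier_log2(c, label, e) for c, e in zip(classes, effects)]
        )
        mu = libs[j] * rel_expr * np.exp2(log2_mult)
        if phi == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / phi
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        sample_meta=sample_meta,
    )
    truth = SimTruth(
        gene_classes=pd.Series(classes, index=gene_ids, name="class"),
        gene_effects=pd.Series(effects, index=gene_ids, name="log2_effect"),
    )
    return matrix, truth


def simulate_annotation(
    truth: SimTruth, pmap: Optional[PathwayMap] = None
) -> GeneAnnotationTable:
    """Minimal annotation table covering the simulated genes."""
    gene_ids = list(truth.gene_classes.index)
    table = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    table["product"] = ["hypothetical protein"] * len(gene_ids)
    table["ec_numbers"] = [[] for _ in gene_ids]
    pathways_of: dict[str, list[str]] = {g: [] for g in gene_ids}
    if pmap is not None:
        for pid, (_, members) in pmap.items():
            for g in members:
                pathways_of.setdefault(g, []).append(pid)
    table["pathway_ids"] = [pathways_of[g] for g in gene_ids]
    table["isoform_group"] = [None] * len(gene_ids)
    return GeneAnnotationTable(table)


def simulate_pathway_map(
    truth: SimTruth,
    n_pathways: int = 30,
    size_range: tuple[int, int] = (15, 90),
    n_enriched: int = 3,
    enrich_factor: float = 16.0,
    rng_seed: int = 0,
) -> tuple[PathwayMap, SimTruth]:
    """Random gene sets, some enriched for planted GSR genes.

    In an enriched pathway each member slot draws a GSR-class gene with
    probability min(1, enrich_factor * gsr_fraction), so the expected
    GSR overlap is size * min(1, enrich_factor * gsr_fraction).
    """
    rng = np.random.default_rng(rng_seed)
    gene_ids = np.asarray(truth.gene_classes.index)
    n_genes = len(gene_ids)
    lo, hi = size_range
    if hi > n_genes:
        raise ValidationError(f"size_range max {hi} exceeds number of genes {n_genes}")
    n_enriched = min(n_enriched, n_pathways)
    gsr_mask = truth.gene_classes.isin(["positive_gsr", "negative_gsr"]).to_numpy()
    gsr_genes = gene_ids[gsr_mask]
    other_genes = gene_ids[~gsr_mask]
    frac_gsr = len(gsr_genes) / n_genes if n_genes else 0.0
    p_gsr = min(1.0, enrich_factor * frac_gsr)

    pmap = PathwayMap()
    for i in range(1, n_pathways + 1):
        pid = f"sp{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        enriched = i <= n_enriched
        if enriched and len(gsr_genes):
            take_gsr = rng.random(size) < p_gsr
            k_gsr = min(int(take_gsr.sum()), len(gsr_genes))
            members = list(rng.choice(gsr_genes, size=k_gsr, replace=False))
            members += list(rng.choice(other_genes, size=size - k_gsr, replace=False))
        else:
            members = list(rng.choice(gene_ids, size=size, replace=False))
        pmap.add(pid, f"Simulated pathway {i}", members)
        truth.pathway_enriched[pid] = bool(enriched)
    return pmap, truth


def simulate_metabolome(
    n_compounds: int = 409,
    frac_dec: float = 0.18,
    log2_effect: float = 3.0,
    noise_sigma: float = 0.2,
    n_reps: int = 6,
    rng_seed: int = 0,
) -> tuple[MetaboliteTable, SimTruth]:
    """Two-condition metabolite intensities with planted differential compounds.

    intensity = baseline * 2^(±log2_effect * 1[high, planted]) *
    LogNormal(0, noise_sigma); m/z uniform in [50, 1200] Da, retention
    time uniform in [0.5, 15] min. Exactly round(frac_dec * n_compounds)
    compounds are planted, with random sign.
    """
    if not (0.0 <= frac_dec <= 1.0):
        raise ValidationError("frac_dec must be in [0, 1]")
    if n_reps < 3:
        raise ValidationError("n_reps must be >= 3")
    rng = np.random.default_rng(rng_seed)
    compound_ids = [f"c{i:04d}" for i in range(1, n_compounds + 1)]

    n_dec = int(round(frac_dec * n_compounds))
    order = rng.permutation(n_compounds)
    classes = np.full(n_compounds, "null", dtype=object)
    effects = np.zeros(n_compounds)
    dec_idx = order[:n_dec]
    signs = rng.choice([-1.0, 1.0], n_dec)
    classes[dec_idx] = np.where(signs > 0, "dec_up", "dec_down")
    effects[dec_idx] = signs * log2_effect

    baseline = rng.lognormal(mean=math.log(1e5), sigma=1.0, size=n_compounds)
    sample_ids, meta_rows = [], []
    for cond in ("low", "high"):
        for rep in range(1, n_reps + 1):
            sample_ids.append(f"{cond}_{rep}")
            meta_rows.append((cond, rep))
    sample_meta = pd.DataFrame(meta_rows, columns=["condition", "replicate"], index=sample_ids)

    data = np.empty((n_compounds, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        is_high = sample_meta.loc[sid, "condition"] == "high"
        mu = baseline * np.exp2(effects if is_high else 0.0)
        data[:, j] = mu * rng.lognormal(mean=0.0, sigma=noise_sigma, size=n_compounds)

    table = MetaboliteTable(
        intensities=pd.DataFrame(data, index=compound_ids, columns=sample_ids),
        mz=pd.Series(rng.uniform(50.0, 1200.0, n_compounds), index=compound_ids, name="mz"),
        rt=pd.Series(rng.uniform(0.5, 15.0, n_compounds), index=compound_ids, name="rt"),
        sample_meta=sample_meta,
    )
    truth = SimTruth(
        compound_classes=pd.Series(classes, index=compound_ids, name="class"),
        compound_effects=pd.Series(effects, index=compound_ids, name="log2_effect"),
    )
    return table, truth
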