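"""Core domain types for the glucose-shift analysis.

The experimental design has four culture conditions of *Chlorella sorokiniana*
grown mixotrophically on glucose:

* ``LL`` — adapted (≥3 subcultures) to low glucose (1.25 g/L),
* ``HH`` — adapted to high glucose (5 g/L),
* ``L2H`` — sampled 36 h after a medium shift from low to high glucose,
* ``H2L`` — sampled 36 h after the reciprocal shift from high to low.

Each condition carries a *target* glucose level: the level the transcriptome
is responding to at sampling time (high for HH and L2H, low for LL and H2L).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Optional, Sequence

import math

import numpy as np
import pandas as pd

LOW_GLUCOSE_G_PER_L = 1.25
HIGH_GLUCOSE_G_PER_L = 5.0

CONDITION_LABELS = ("LL", "HH", "L2H", "H2L")


@dataclass(frozen=True)
class Condition:
    """One of the four culture conditions; the label determines everything."""

    label: str
    glucose_level: float  # g/L of the medium the sample sits in
    is_shifted: bool
    target_level: float  # g/L level the transcriptome responds to

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        try:
            return CONDITIONS[label]
        except KeyError:
            raise ValueError(
                f"unknown condition label {label!r}; allowed labels are "
                f"{', '.join(CONDITION_LABELS)}"
            ) from None

    @property
    def target_is_high(self) -> bool:
        return self.target_level == HIGH_GLUCOSE_G_PER_L


CONDITIONS: Mapping[str, Condition] = {
    "LL": Condition("LL", LOW_GLUCOSE_G_PER_L, False, LOW_GLUCOSE_G_PER_L),
    "HH": Condition("HH", HIGH_GLUCOSE_G_PER_L, False, HIGH_GLUCOSE_G_PER_L),
    "L2H": Condition("L2H", HIGH_GLUCOSE_G_PER_L, True, HIGH_GLUCOSE_G_PER_L),
    "H2L": Condition("H2L", LOW_GLUCOSE_G_PER_L, True, LOW_GLUCOSE_G_PER_L),
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class CountMatrix:
    """Gene × sample read-count matrix with per-sample condition metadata.

    ``counts`` is a genes × samples DataFrame of non-negative integers.
    ``sample_meta`` is indexed by sample id with columns ``condition``
    (label string) and ``replicate`` (int). ``effective_lengths`` are
    per-gene transcript lengths in nucleotides used for TPM; they default
    to 1,000 nt, which makes TPM proportional to counts.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    effective_lengths: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.effective_lengths is None:
            self.effective_lengths = pd.Series(
                1000.0, index=self.counts.index, name="effective_length"
            )
        self.validate()

    # -- contracts -----------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"count for gene {c.index[i]!r} in sample {c.columns[j]!r} "
                f"is {arr[i, j]!r}: counts must be non-negative integers"
            )
        missing = set(c.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        for label in self.sample_meta["condition"]:
            Condition.from_label(label)
        if (np.asarray(self.effective_lengths) <= 0).any():
            raise ValidationError("effective lengths must be positive")

    # -- accessors -----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def condition_labels(self) -> set[str]:
        return set(self.sample_meta.loc[self.sample_ids, "condition"])

    def samples_for(self, label: str) -> list[str]:
        Condition.from_label(label)
        meta = self.sample_meta.loc[self.sample_ids]
        return list(meta.index[meta["condition"] == label])

    def require_conditions(self, labels: Iterable[str], min_replicates: int = 2) -> None:
        for label in labels:
            samples = self.samples_for(label)
            if not samples:
                raise ValidationError(f"condition {label!r} is missing from the matrix")
            if len(samples) < min_replicates:
                raise ValidationError(
                    f"condition {label!r} has {len(samples)} replicate(s); "
                    f"at least {min_replicates} are required"
                )

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class GeneAnnotationTable:
    """Per-gene functional annotation: product, EC numbers, pathways, isoform group.

    Stored as a DataFrame indexed by gene id with columns ``product``
    (free text), ``ec_numbers`` (list of EC strings), ``pathway_ids``
    (list of pathway ids) and ``isoform_group`` (shared id or None).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate gene ids in annotation table")
        for col, default in (
            ("product", ""),
            ("ec_numbers", None),
            ("pathway_ids", None),
            ("isoform_group", None),
        ):
            if col not in self.table.columns:
                self.table[col] = [default] * len(self.table)
        self.table["ec_numbers"] = [
            list(v) if isinstance(v, (list, tuple, set)) else ([] if v in (None, "") else [v])
            for v in self.table["ec_numbers"]
        ]
        self.table["pathway_ids"] = [
            list(v) if isinstance(v, (list, tuple, set)) else ([] if v in (None, "") else [v])
            for v in self.table["pathway_ids"]
        ]

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def groups(self, key: str) -> dict[str, list[str]]:
        """Map group id -> member gene ids for ``key`` in {'isoform_group','ec'}."""
        out: dict[str, list[str]] = {}
        if key == "isoform_group":
            for gid, grp in self.table["isoform_group"].items():
                if grp not in (None, ""):
                    out.setdefault(str(grp), []).append(gid)
        elif key == "ec":
            for gid, ecs in self.table["ec_numbers"].items():
                for ec in ecs:
                    out.setdefault(ec, []).append(gid)
        else:
            raise ValueError("group key must be 'isoform_group' or 'ec'")
        return out


@dataclass
class PathwayMap:
    """pathway id -> (name, member gene ids). GMT-style gene sets."""

    pathways: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __contains__(self, pid: str) -> bool:
        return pid in self.pathways

    def __len__(self) -> int:
        return len(self.pathways)

    def items(self):
        return self.pathways.items()

    def name(self, pid: str) -> str:
        return self.pathways[pid][0]

    def members(self, pid: str) -> frozenset[str]:
        return self.pathways[pid][1]

    def add(self, pid: str, name: str, members: Iterable[str]) -> None:
        self.pathways[pid] = (name, frozenset(members))

    def validate_against(self, gene_universe: Iterable[str]) -> None:
        universe = set(gene_universe)
        for pid, (_, members) in self.pathways.items():
            extra = members - universe
            if extra:
                raise ValidationError(
                    f"pathway {pid!r} has members outside the transcriptome: "
                    f"{sorted(extra)[:5]}"
                )


@dataclass
class MetaboliteTable:
    """Compound × sample LC-MS intensity table.

    ``intensities`` is compounds × samples (positive reals); ``mz`` and
    ``rt`` are per-compound mass-to-charge (Da) and retention time (min);
    ``sample_meta`` maps sample id -> condition label ("low"/"high"
    glucose) and replicate. ``annotation`` optionally holds a KEGG
    compound id or pathway per compound.
    """

    intensities: pd.DataFrame
    mz: pd.Series
    rt: pd.Series
    sample_meta: pd.DataFrame
    annotation: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.intensities.index.duplicated().any():
            raise ValidationError("duplicate compound ids")
        if (self.intensities.to_numpy() < 0).any():
            raise ValidationError("negative intensity")
        missing = set(self.intensities.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")

    @property
    def compound_ids(self) -> pd.Index:
        return self.intensities.index

    def samples_for(self, condition: str) -> list[str]:
        meta = self.sample_meta.loc[self.intensities.columns]
        return list(meta.index[meta["condition"] == condition])

    def conditions(self) -> list[str]:
        return sorted(set(self.sample_meta.loc[self.intensities.columns, "condition"]))

    def subset(self, compound_ids: Sequence[str]) -> "MetaboliteTable":
        return MetaboliteTable(
            intensities=self.intensities.loc[compound_ids],
            mz=self.mz.loc[compound_ids],
            rt=self.rt.loc[compound_ids],
            sample_meta=self.sample_meta,
            annotation=None if self.annotation is None else self.annotation.loc[compound_ids],
        )


@dataclass
class AnalysisConfig:
    """All thresholds of the analysis, with the study's published defaults.

    deg_fold/deg_fdr: DEG call (fold-change > 4, BH-FDR q < 0.01).
    summative_fold/summative_p: significance on summed isoform levels
    (fold > 2, raw p < 0.05). moderate_fold: the 1.2-fold "moderate"
    grade used in pathway heatmaps. dec_fold/dec_p: differential
    metabolite call (fold > 4, p < 0.01). rsd_max_percent: LC-MS QC
    filter (RSD > 30% removed). ppm_max: mass-accuracy filter (< 10 ppm).
    pseudocount is added to mean abundances before log-ratios.
    """

    deg_fold: float = 4.0
    deg_fdr: float = 0.01
    summative_fold: float = 2.0
    summative_p: float = 0.05
    moderate_fold: float = 1.2
    dec_fold: float = 4.0
    dec_p: float = 0.01
    rsd_max_percent: float = 30.0
    ppm_max: float = 10.0
    pseudocount: float = 0.5
    top_n: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deg_fold", "summative_fold", "moderate_fold", "dec_fold"):
            if getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be > 1")
        for name in ("deg_fdr", "summative_p", "dec_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)  # type: ignore[arg-type]

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)

    @property
    def log2_deg_fold(self) -> float:
        return math.log2(self.deg_fold)

    @property
    def log2_summative_fold(self) -> float:
        return math.log2(self.summative_fold)

    @property
    def log2_moderate_fold(self) -> float:
        return math.log2(self.moderate_fold)

    @property
    def log2_dec_fold(self) -> float:
        return math.log2(self.dec_fold)
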