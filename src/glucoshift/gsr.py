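"""Glucose-specific responsive (GSR) gene identification.

A GSR gene is significantly differentially expressed in BOTH reciprocal
shift comparisons (L2H vs LL and H2L vs HH) and responds monotonically to
the glucose level: up on the shift to high glucose and down on the shift
to low (positive correlation with glucose), or the reverse (negative
correlation). Genes significant in both shifts but moving the same way in
both — a transient shift response — are non-monotonic and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .diffexpr import DEGRecord, call_degs
from .types import AnalysisConfig, CountMatrix, ValidationError

SHIFT_LOW_TO_HIGH = ("LL", "L2H")  # comparison A=LL, B=L2H
SHIFT_HIGH_TO_LOW = ("HH", "H2L")
STEADY_STATE = ("LL", "HH")

COMPARISON_NAMES = ("L2H_vs_LL", "H2L_vs_HH", "HH_vs_LL")


@dataclass
class GSRRecord:
    gene_id: str
    lfc_l2h_vs_ll: float
    lfc_h2l_vs_hh: float
    lfc_hh_vs_ll: float
    classification: str  # positive_gsr | negative_gsr | non_monotonic
    rank_score: float  # |lfc_hh_vs_ll|


@dataclass
class VennSummary:
    """Sizes of the three DEG sets, their intersections, and the monotonic call."""

    n_l2h_vs_ll: int
    n_h2l_vs_hh: int
    n_hh_vs_ll: int
    n_l2h_and_h2l: int
    n_l2h_and_hh: int
    n_h2l_and_hh: int
    n_all_three: int
    n_common_shift: int  # = n_l2h_and_h2l
    n_monotonic: int
    monotonic_percent: float

    @staticmethod
    def percent_monotonic(n_common: int, n_monotonic: int) -> float:
        """100 * monotonic/common, rounded to 1 decimal for reports."""
        if n_common == 0:
            return 0.0
        return round(100.0 * n_monotonic / n_common, 1)

    @staticmethod
    def percent_deg(n_deg: int, n_genes: int) -> float:
        """DEG fraction of the transcriptome as a percentage (2 decimals)."""
        return round(100.0 * n_deg / n_genes, 2)


def build_comparisons(
    matrix: CountMatrix, config: AnalysisConfig
) -> dict[str, list[DEGRecord]]:
    """DEG calling for the three design comparisons.

    Returns records keyed "L2H_vs_LL", "H2L_vs_HH", "HH_vs_LL"; each
    log2fc is oriented second-named-over-first per the diffexpr
    convention (A, B) with B the shifted/steady high state.
    """
    for label in ("LL", "HH", "L2H", "H2L"):
        if label not in matrix.condition_labels():
            raise ValidationError(f"condition {label!r} is missing from the matrix")
    return {
        "L2H_vs_LL": call_degs(matrix, SHIFT_LOW_TO_HIGH, config),
        "H2L_vs_HH": call_degs(matrix, SHIFT_HIGH_TO_LOW, config),
        "HH_vs_LL": call_degs(matrix, STEADY_STATE, config),
    }


def _significant(rec: DEGRecord) -> bool:
    return rec.reg_class in ("significant_up", "significant_down")


def identify_gsr(
    deg_lists: dict[str, list[DEGRecord]], config: AnalysisConfig
) -> tuple[list[GSRRecord], VennSummary]:
    """Intersect the shift DEG sets and classify monotonic direction.

    positive_gsr: up on shift to high (lfc_L2H_vs_LL > 0) and down on
    shift to low (lfc_H2L_vs_HH < 0); negative_gsr is the mirror. A gene
    also significant in HH vs LL must agree in sign with its L2H
    response, otherwise it is non_monotonic.
    """
    by_gene = {}
    universes = []
    for name in COMPARISON_NAMES:
        if name not in deg_lists:
            raise ValidationError(f"missing comparison {name!r}")
        recs = {r.gene_id: r for r in deg_lists[name]}
        by_gene[name] = recs
        universes.append(set(recs))
    if not (universes[0] == universes[1] == universes[2]):
        raise ValidationError("DEG lists cover different gene universes")

    sig = {name: {g for g, r in by_gene[name].items() if _significant(r)} for name in COMPARISON_NAMES}
    common = sig["L2H_vs_LL"] & sig["H2L_vs_HH"]

    records = []
    n_monotonic = 0
    for gid in sorted(common):
        l2h = by_gene["L2H_vs_LL"][gid]
        h2l = by_gene["H2L_vs_HH"][gid]
        hh = by_gene["HH_vs_LL"][gid]
        if l2h.log2fc > 0 and h2l.log2fc < 0:
            cls = "positive_gsr"
        elif l2h.log2fc < 0 and h2l.log2fc > 0:
            cls = "negative_gsr"
        else:
            cls = "non_monotonic"
        if cls != "non_monotonic" and gid in sig["HH_vs_LL"]:
            if (hh.log2fc > 0) != (l2h.log2fc > 0):
                cls = "non_monotonic"
        if cls != "non_monotonic":
            n_monotonic += 1
        records.append(
            GSRRecord(
                gene_id=gid,
                lfc_l2h_vs_ll=l2h.log2fc,
                lfc_h2l_vs_hh=h2l.log2fc,
                lfc_hh_vs_ll=hh.log2fc,
                classification=cls,
                rank_score=abs(hh.log2fc),
            )
        )

    s1, s2, s3 = sig["L2H_vs_LL"], sig["H2L_vs_HH"], sig["HH_vs_LL"]
    summary = VennSummary(
        n_l2h_vs_ll=len(s1),
        n_h2l_vs_hh=len(s2),
        n_hh_vs_ll=len(s3),
        n_l2h_and_h2l=len(s1 & s2),
        n_l2h_and_hh=len(s1 & s3),
        n_h2l_and_hh=len(s2 & s3),
        n_all_three=len(s1 & s2 & s3),
        n_common_shift=len(common),
        n_monotonic=n_monotonic,
        monotonic_percent=VennSummary.percent_monotonic(len(common), n_monotonic),
    )
    return records, summary


def gsr_gene_set(records: Sequence[GSRRecord]) -> set[str]:
    """Monotonic (positive or negative) GSR gene ids."""
    return {r.gene_id for r in records if r.classification != "non_monotonic"}


def rank_top(records: Sequence[GSRRecord], direction: str, n: int) -> list[GSRRecord]:
    """Top-n GSR genes by |steady-state log2fc|, like the Fig-3F-style ranking.

    "up" ranks positive_gsr genes, "down" negative_gsr; ties break on
    lexicographically smaller gene id.
    """
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    wanted = "positive_gsr" if direction == "up" else "negative_gsr"
    pool = [r for r in records if r.classification == wanted]
    pool.sort(key=lambda r: (-r.rank_score, r.gene_id))
    return pool[: max(0, n)]
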