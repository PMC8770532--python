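"""Glucose-assimilation route inference from transcript and metabolite calls.

Candidate routes from glucose to pyruvate are encoded as small pathway
graphs (compound -> enzyme -> compound): the upper and lower halves of
Embden-Meyerhof-Parnas glycolysis (EMP), the Entner-Doudoroff (ED)
pathway, and the oxidative pentose phosphate (OPP) pathway, plus starch
biosynthesis. Enzymes are identified by EC number; their regulation is
graded from summative isoform-level transcription, metabolites from DEC
calls, both on a tri-state scale (significant / moderate / unchanged,
with direction). A route's preference score is the pathway-consistency
p-value of its largest co-directional enzyme count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .diffexpr import SummativeRecord
from .enrichment import ConsistencyResult, pathway_consistency, pathway_enrichment
from .gsr import GSRRecord
from .metabolome import DECRecord
from .types import AnalysisConfig, PathwayMap, ValidationError


@dataclass
class PathwayGraph:
    """A small metabolic route: EC-numbered enzymes and their compounds.

    ``absent_enzymes`` are ECs drawn in the route but not found in the
    transcriptome; they stay in the graph (grade "missing") and are
    excluded from consistency counts.
    """

    name: str
    enzymes: tuple[str, ...]
    absent_enzymes: tuple[str, ...] = ()
    compounds: tuple[str, ...] = ()
    # (substrate, ec, product) triples; descriptive, not used in scoring
    edges: tuple[tuple[str, str, str], ...] = ()

    @property
    def all_enzymes(self) -> tuple[str, ...]:
        return self.enzymes + self.absent_enzymes


def builtin_graphs() -> dict[str, PathwayGraph]:
    """The five hard-coded route graphs with their catalogued EC numbers."""
    return {
        "EMP_upper": PathwayGraph(
            name="EMP_upper",
            enzymes=("5.3.1.9", "3.1.3.11", "4.1.2.13", "5.3.1.1"),
            compounds=(
                "glucose",
                "glucose-6-phosphate",
                "fructose-6-phosphate",
                "fructose-1,6-bisphosphate",
                "glyceraldehyde-3-phosphate",
                "dihydroxyacetone-phosphate",
            ),
            edges=(
                ("glucose-6-phosphate", "5.3.1.9", "fructose-6-phosphate"),
                ("fructose-1,6-bisphosphate", "3.1.3.11", "fructose-6-phosphate"),
                ("fructose-1,6-bisphosphate", "4.1.2.13", "glyceraldehyde-3-phosphate"),
                ("dihydroxyacetone-phosphate", "5.3.1.1", "glyceraldehyde-3-phosphate"),
            ),
        ),
        "ED": PathwayGraph(
            name="ED",
            enzymes=("2.7.1.12", "1.1.1.49", "3.1.1.31"),
            absent_enzymes=("1.1.5.2", "4.1.2.14", "4.2.1.12"),
            compounds=(
                "glucose",
                "gluconate",
                "gluconate-6-phosphate",
                "glucose-6-phosphate",
                "gluconolactone-6-phosphate",
                "2-keto-3-deoxy-gluconate-6-phosphate",
                "pyruvate",
                "glyceraldehyde-3-phosphate",
            ),
            edges=(
                ("glucose", "1.1.5.2", "gluconate"),
                ("gluconate", "2.7.1.12", "gluconate-6-phosphate"),
                ("glucose-6-phosphate", "1.1.1.49", "gluconolactone-6-phosphate"),
                ("gluconolactone-6-phosphate", "3.1.1.31", "gluconate-6-phosphate"),
                ("gluconate-6-phosphate", "4.2.1.12", "2-keto-3-deoxy-gluconate-6-phosphate"),
                ("2-keto-3-deoxy-gluconate-6-phosphate", "4.1.2.14", "pyruvate"),
            ),
        ),
        "OPP": PathwayGraph(
            name="OPP",
            enzymes=("1.1.1.44", "5.1.3.1", "5.3.1.6", "2.2.1.1", "2.2.1.2", "2.7.1.15"),
            # shared entry reactions with ED (counted there)
            absent_enzymes=(),
            compounds=(
                "gluconate-6-phosphate",
                "ribulose-5-phosphate",
                "xylulose-5-phosphate",
                "ribose-5-phosphate",
                "sedoheptulose-7-phosphate",
                "fructose-6-phosphate",
                "glyceraldehyde-3-phosphate",
                "ribose",
            ),
            edges=(
                ("gluconate-6-phosphate", "1.1.1.44", "ribulose-5-phosphate"),
                ("ribulose-5-phosphate", "5.1.3.1", "xylulose-5-phosphate"),
                ("ribulose-5-phosphate", "5.3.1.6", "ribose-5-phosphate"),
                ("ribose", "2.7.1.15", "ribose-5-phosphate"),
                ("xylulose-5-phosphate", "2.2.1.1", "sedoheptulose-7-phosphate"),
                ("sedoheptulose-7-phosphate", "2.2.1.2", "fructose-6-phosphate"),
            ),
        ),
        "EMP_lower": PathwayGraph(
            name="EMP_lower",
            enzymes=("1.2.1.12", "2.7.2.3", "4.2.1.11", "2.7.1.40"),
            compounds=(
                "glyceraldehyde-3-phosphate",
                "glycerate-1,3-bisphosphate",
                "glycerate-3-phosphate",
                "glycerate-2-phosphate",
                "phosphoenolpyruvate",
                "pyruvate",
            ),
            edges=(
                ("glyceraldehyde-3-phosphate", "1.2.1.12", "glycerate-1,3-bisphosphate"),
                ("glycerate-1,3-bisphosphate", "2.7.2.3", "glycerate-3-phosphate"),
                ("glycerate-2-phosphate", "4.2.1.11", "phosphoenolpyruvate"),
                ("phosphoenolpyruvate", "2.7.1.40", "pyruvate"),
            ),
        ),
        "starch_biosynthesis": PathwayGraph(
            name="starch_biosynthesis",
            enzymes=("5.4.2.2", "2.7.7.27", "2.4.1.242", "2.4.1.18"),
            compounds=(
                "glucose-6-phosphate",
                "glucose-1-phosphate",
                "ADP-glucose",
                "amylose",
                "starch",
            ),
            edges=(
                ("glucose-6-phosphate", "5.4.2.2", "glucose-1-phosphate"),
                ("glucose-1-phosphate", "2.7.7.27", "ADP-glucose"),
                ("ADP-glucose", "2.4.1.242", "amylose"),
                ("amylose", "2.4.1.18", "starch"),
            ),
        ),
    }


@dataclass
class RegulationCall:
    node_id: str  # EC number or compound id
    grade: str  # significant | moderate | unchanged | missing
    direction: str  # up | down | none
    source: str  # summative_transcript | metabolite
    discordant: bool = False


@dataclass
class RouteVerdict:
    pathway: str
    n_enzymes: int  # enzymes with data
    m_same: int  # largest co-directional count (significant + moderate)
    direction: str
    p_value: float
    supporting_metabolites: list[str] = field(default_factory=list)
    conflicting_metabolites: list[str] = field(default_factory=list)
    preferred: bool = False
    warning: str = ""


def _split_class(reg_class: str) -> tuple[str, str]:
    """reg_class string -> (grade, direction)."""
    if reg_class.endswith("_up"):
        return reg_class[:-3], "up"
    if reg_class.endswith("_down"):
        return reg_class[:-5], "down"
    return "unchanged", "none"


def call_enzymes(
    graph: PathwayGraph,
    summative_by_ec: Mapping[str, SummativeRecord],
) -> list[RegulationCall]:
    """Tri-state transcriptional call per enzyme from its summative record."""
    calls = []
    for ec in graph.all_enzymes:
        rec = summative_by_ec.get(ec)
        if rec is None or ec in graph.absent_enzymes:
            calls.append(RegulationCall(ec, "missing", "none", "summative_transcript"))
            continue
        grade, direction = _split_class(rec.reg_class)
        calls.append(
            RegulationCall(ec, grade, direction, "summative_transcript", rec.discordant)
        )
    return calls


def call_metabolites(
    graph: PathwayGraph,
    decs: Sequence[DECRecord],
    config: Optional[AnalysisConfig] = None,
) -> list[RegulationCall]:
    """Tri-state call per graph compound from DEC records.

    "significant" uses the DEC thresholds (fold > dec_fold, p < dec_p);
    "moderate" only needs |fold| > moderate_fold. Compounds absent from
    the measured table are "missing".
    """
    config = config or AnalysisConfig()
    by_id = {d.compound_id: d for d in decs}
    calls = []
    for cid in graph.compounds:
        d = by_id.get(cid)
        if d is None:
            calls.append(RegulationCall(cid, "missing", "none", "metabolite"))
            continue
        if abs(d.log2fc) > config.log2_dec_fold and d.p_value < config.dec_p:
            grade = "significant"
        elif abs(d.log2fc) > config.log2_moderate_fold:
            grade = "moderate"
        else:
            grade = "unchanged"
        direction = "none" if grade == "unchanged" else ("up" if d.log2fc > 0 else "down")
        calls.append(RegulationCall(cid, grade, direction, "metabolite"))
    return calls


def evaluate_route(
    graph: PathwayGraph,
    enzyme_calls: Sequence[RegulationCall],
    metabolite_calls: Sequence[RegulationCall] = (),
) -> RouteVerdict:
    """Score one route: co-directional enzyme count and its consistency p.

    N counts enzymes with data (grade != missing); M is the larger of
    the up- and down-regulated counts among significant-or-moderate
    enzymes. Metabolites changed in the enzyme-majority direction are
    "supporting", those changed against it "conflicting".
    """
    with_data = [c for c in enzyme_calls if c.grade != "missing"]
    n = len(with_data)
    up = sum(1 for c in with_data if c.grade in ("significant", "moderate") and c.direction == "up")
    down = sum(
        1 for c in with_data if c.grade in ("significant", "moderate") and c.direction == "down"
    )
    if n == 0:
        return RouteVerdict(
            graph.name, 0, 0, "none", 1.0, warning="no enzyme in this route has data"
        )
    if up >= down:
        m, direction = up, ("up" if up > 0 else "none")
    else:
        m, direction = down, "down"
    consistency = pathway_consistency(n, m, direction)
    supporting, conflicting = [], []
    for c in metabolite_calls:
        if c.grade in ("significant", "moderate") and direction in ("up", "down"):
            (supporting if c.direction == direction else conflicting).append(c.node_id)
    return RouteVerdict(
        pathway=graph.name,
        n_enzymes=n,
        m_same=m,
        direction=direction,
        p_value=consistency.p_value,
        supporting_metabolites=sorted(supporting),
        conflicting_metabolites=sorted(conflicting),
    )


def compare_routes(verdicts: Sequence[RouteVerdict], alpha: float = 0.05) -> tuple[list[RouteVerdict], str]:
    """Mark the preferred route and render a neutral textual report.

    Preferred = upregulated route with the smallest consistency p-value
    below ``alpha``; ties break on larger M, then pathway name.
    """
    if len(verdicts) < 2:
        raise ValidationError("need at least two route verdicts to compare")
    for v in verdicts:
        v.preferred = False
    candidates = [v for v in verdicts if v.direction == "up" and v.p_value < alpha]
    if candidates:
        best = sorted(candidates, key=lambda v: (v.p_value, -v.m_same, v.pathway))[0]
        best.preferred = True
    lines = []
    for v in sorted(verdicts, key=lambda v: (v.p_value, v.pathway)):
        mark = " [preferred]" if v.preferred else ""
        lines.append(
            f"{v.pathway}: {v.m_same} of {v.n_enzymes} enzymes co-directional "
            f"({v.direction}), p = {v.p_value:.3g}{mark}"
        )
        if v.supporting_metabolites:
            lines.append(f"  supporting metabolites: {', '.join(v.supporting_metabolites)}")
        if v.conflicting_metabolites:
            lines.append(f"  conflicting metabolites: {', '.join(v.conflicting_metabolites)}")
        if v.warning:
            lines.append(f"  warning: {v.warning}")
    return list(verdicts), "\n".join(lines)


@dataclass
class PathwayDirectionReport:
    pathway_id: str
    name: str
    n_gsr: int
    m_same: int
    direction: str
    p_value: float
    enrichment_p: float
    fc_log2: float


def gsr_function_report(
    gsr_records: Sequence[GSRRecord],
    pmap: PathwayMap,
    transcriptome_size: int,
) -> list[PathwayDirectionReport]:
    """Enrichment plus direction consistency of GSR genes per pathway.

    For each pathway, N = GSR genes annotated to it, M = count in the
    majority GSR direction (positive vs negative correlation with
    glucose), p = pathway_consistency(N, M).
    """
    monotonic = [r for r in gsr_records if r.classification != "non_monotonic"]
    gene_set = {r.gene_id for r in monotonic}
    by_gene = {r.gene_id: r for r in monotonic}
    enr = {e.pathway_id: e for e in pathway_enrichment(gene_set, pmap, transcriptome_size)}
    reports = []
    for pid, (name, members) in pmap.items():
        inside = sorted(members & gene_set)
        n = len(inside)
        pos = sum(1 for g in inside if by_gene[g].classification == "positive_gsr")
        neg = n - pos
        if n == 0:
            reports.append(
                PathwayDirectionReport(pid, name, 0, 0, "none", 1.0, 1.0, float("nan"))
            )
            continue
        if pos >= neg:
            m, direction = pos, "up"
        else:
            m, direction = neg, "down"
        cons = pathway_consistency(n, m, direction)
        e = enr[pid]
        reports.append(
            PathwayDirectionReport(
                pid, name, n, m, direction, cons.p_value, e.p_value, e.fc_log2
            )
        )
    reports.sort(key=lambda r: (r.enrichment_p, r.pathway_id))
    return reports
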