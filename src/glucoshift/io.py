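"""Readers and writers for the pipeline's tabular formats.

All text formats are tab-separated UTF-8 with ``#`` comment lines ignored,
except the metabolite table (CSV) and pathway maps (GMT dialect). Result
collections are written as TSV (>= 6 significant digits) plus a JSON
sidecar with full float precision so downstream consumers never depend on
TSV rounding.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    AnalysisConfig,
    Condition,
    CountMatrix,
    GeneAnnotationTable,
    MetaboliteTable,
    PathwayMap,
    ValidationError,
)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_count_matrix(path, meta_path, lengths_path=None) -> CountMatrix:
    """Read a gene × sample count TSV plus a sample-metadata TSV.

    The count table has the gene id in the first column; the metadata
    table has columns ``sample_id``, ``condition``, ``replicate``.
    """
    raw = _read_tsv(path)
    gene_col = raw.columns[0]
    counts = raw.set_index(gene_col)
    # validate cell-by-cell so errors can name the offending cell
    parsed = {}
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals.fillna(-1)))
        if bad.any():
            gene = counts.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"count for gene {gene!r} in sample {col!r} is "
                f"{counts.loc[gene, col]!r}: counts must be non-negative integers"
            )
        parsed[col] = vals.astype(np.int64)
    counts = pd.DataFrame(parsed, index=counts.index)

    meta = _read_tsv(meta_path)
    required = {"sample_id", "condition", "replicate"}
    if not required.issubset(meta.columns):
        raise ValidationError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    meta["replicate"] = meta["replicate"].astype(int)
    for label in meta["condition"]:
        Condition.from_label(label)

    lengths = None
    if lengths_path is not None:
        lt = _read_tsv(lengths_path)
        lengths = lt.set_index(lt.columns[0]).iloc[:, 0].astype(float)
        lengths = lengths.reindex(counts.index)

    return CountMatrix(counts=counts, sample_meta=meta, effective_lengths=lengths)


def write_count_matrix(matrix: CountMatrix, path, meta_path) -> None:
    matrix.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    (
        matrix.sample_meta.rename_axis("sample_id")
        .reset_index()[["sample_id", "condition", "replicate"]]
        .to_csv(meta_path, sep="\t", index=False)
    )


def read_pathway_map(path) -> PathwayMap:
    """Parse a GMT-dialect file: id <tab> name <tab> member ids."""
    pmap = PathwayMap()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields "
                    f"(id, name, members...), got {len(parts)}"
                )
            pid, name, *members = parts
            pmap.add(pid, name, [m for m in members if m])
    return pmap


def write_pathway_map(pmap: PathwayMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, (name, members) in pmap.items():
            fh.write("\t".join([pid, name, *sorted(members)]) + "\n")


def read_annotation(path) -> GeneAnnotationTable:
    """Annotation TSV: gene_id, product, ec_numbers (';'-joined),
    pathway_ids (';'-joined), isoform_group."""
    raw = _read_tsv(path).set_index("gene_id")
    table = pd.DataFrame(index=raw.index)
    table["product"] = raw.get("product", pd.Series("", index=raw.index)).fillna("")
    table["ec_numbers"] = [
        [x for x in str(v).split(";") if x and x != "nan"]
        for v in raw.get("ec_numbers", pd.Series("", index=raw.index)).fillna("")
    ]
    table["pathway_ids"] = [
        [x for x in str(v).split(";") if x and x != "nan"]
        for v in raw.get("pathway_ids", pd.Series("", index=raw.index)).fillna("")
    ]
    iso = raw.get("isoform_group", pd.Series("", index=raw.index)).fillna("")
    table["isoform_group"] = [v if v else None for v in iso]
    return GeneAnnotationTable(table)


def write_annotation(ann: GeneAnnotationTable, path) -> None:
    out = pd.DataFrame(index=ann.table.index)
    out["product"] = ann.table["product"]
    out["ec_numbers"] = [";".join(v) for v in ann.table["ec_numbers"]]
    out["pathway_ids"] = [";".join(v) for v in ann.table["pathway_ids"]]
    out["isoform_group"] = [v or "" for v in ann.table["isoform_group"]]
    out.rename_axis("gene_id").to_csv(path, sep="\t")


def read_metabolite_table(path, meta_path) -> MetaboliteTable:
    """Metabolite CSV: compound_id, mz, rt, then one column per sample."""
    raw = pd.read_csv(path, comment="#").set_index("compound_id")
    mz = raw["mz"].astype(float)
    rt = raw["rt"].astype(float)
    annotation = raw["annotation"] if "annotation" in raw.columns else None
    sample_cols = [c for c in raw.columns if c not in ("mz", "rt", "annotation")]
    intensities = raw[sample_cols].astype(float)
    meta = pd.read_csv(meta_path, comment="#").set_index("sample_id")
    meta["replicate"] = meta["replicate"].astype(int)
    return MetaboliteTable(
        intensities=intensities, mz=mz, rt=rt, sample_meta=meta, annotation=annotation
    )


def write_metabolite_table(table: MetaboliteTable, path, meta_path) -> None:
    out = pd.DataFrame({"mz": table.mz, "rt": table.rt})
    if table.annotation is not None:
        out["annotation"] = table.annotation
    out = out.join(table.intensities)
    out.rename_axis("compound_id").to_csv(path)
    table.sample_meta.rename_axis("sample_id").reset_index().to_csv(meta_path, index=False)


def load_config(path) -> AnalysisConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError("config YAML must be a mapping")
    return AnalysisConfig.from_dict(data)


def save_config(config: AnalysisConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


# -- generic result tables --------------------------------------------------


def _record_to_dict(rec: Any) -> dict:
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        d = dataclasses.asdict(rec)
    elif isinstance(rec, dict):
        d = dict(rec)
    else:
        raise TypeError(f"unsupported record type {type(rec)!r}")
    out = {}
    for k, v in d.items():
        if isinstance(v, (list, tuple, set, frozenset)):
            out[k] = ";".join(map(str, sorted(v) if isinstance(v, (set, frozenset)) else v))
        else:
            out[k] = v
    return out


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON-serializable: {type(o)!r}")


def write_results_table(records: Sequence[Any], path, field_names: Optional[list[str]] = None) -> None:
    """Write a homogeneous record collection as TSV + full-precision JSON sidecar.

    Floats in the TSV carry >= 6 significant digits; the sidecar at
    ``<path>.json`` is authoritative for numeric round-trips.
    """
    path = Path(path)
    dicts = [_record_to_dict(r) for r in records]
    if field_names is None:
        if dicts:
            field_names = list(dicts[0].keys())
        elif records or field_names is None:
            field_names = list(dicts[0].keys()) if dicts else []
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(field_names) + "\n")
        for d in dicts:
            row = []
            for k in field_names:
                v = d.get(k, "")
                if isinstance(v, float):
                    row.append(f"{v:.6g}")
                else:
                    row.append(str(v))
            fh.write("\t".join(row) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(
            [{k: d.get(k) for k in field_names} for d in dicts]
            if field_names
            else dicts,
            fh,
            indent=1,
            default=_json_default,
        )


def read_results_json(path) -> list[dict]:
    with open(Path(str(path) + ".json") if not str(path).endswith(".json") else path) as fh:
        return json.load(fh)
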