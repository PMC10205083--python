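"""Readers and writers for every table schema the package consumes.

Text formats only: tab-separated tables for counts/annotations, GMT for
gene sets, comma-separated tables for enrichments, OCR traces and flux
panels, JSON for study summaries and ledgers.  All writers use UTF-8,
headers, and 6-significant-digit floats so outputs are byte-stable for a
fixed configuration and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .species_scaling import GeneSetCollection

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_sample_sheet", "read_species_sheet",
    "read_ortholog_map", "read_gmt", "write_gmt",
    "read_enrichment_csv", "write_enrichment_csv", "enrichment_wide",
    "read_ocr_csv", "write_ocr_csv",
    "read_panel_csv", "write_panel_csv",
    "write_table", "write_json",
]

FLOAT_FORMAT = "%.6g"


def _require_columns(df: pd.DataFrame, needed: list[str], what: str,
                     path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{what} {path}: missing required column(s) "
                         f"{missing}; found {list(df.columns)}")


def read_counts_tsv(path) -> pd.DataFrame:
    """Gene x sample counts: first column ``gene_id``, then sample ids."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError(f"counts {path}: first column must be 'gene_id', "
                         f"got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).to_numpy().nonzero()[0][0]) + 2
        raise ValueError(f"counts {path}: malformed row near line {bad}")
    return df


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    df.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "species"], "sample sheet", path)
    return df


def read_species_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["species", "body_mass_g"], "species sheet", path)
    return df


def read_ortholog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["species", "source_gene_id", "reference_symbol"],
                     "ortholog map", path)
    return df


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: name, description, then tab-separated member symbols."""
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"GMT {path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields (name, description, members), got {len(parts)}")
            name, desc, *members = parts
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"GMT {path}: line {lineno}: duplicate set "
                                 f"name {name!r}")
            if not members:
                raise ValueError(f"GMT {path}: line {lineno}: set {name!r} "
                                 "has no members")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets:
            desc = sets.descriptions.get(name, "")
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


_ENRICH_COLS = ["sample_id", "species", "compartment", "analyte", "fragment",
                "ape", "time_min"]


def read_enrichment_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, _ENRICH_COLS, "enrichment table", path)
    return df


def write_enrichment_csv(df: pd.DataFrame, path) -> None:
    df[_ENRICH_COLS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def enrichment_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long enrichment schema to one row per sample.

    Columns are the ``<analyte>_<fragment>`` observables the flux model
    consumes (``alanine_c3``, ``malate_total``, ..., ``glucose_m7h``);
    repeated measurements of one observable (e.g. the three late plasma
    time points) are averaged.
    """
    long = long.copy()
    long["observable"] = long["analyte"] + "_" + long["fragment"]
    wide = long.pivot_table(index=["sample_id", "species"],
                            columns="observable", values="ape",
                            aggfunc="mean")
    return wide.reset_index().rename_axis(columns=None)


_OCR_COLS = ["well", "time_min", "ocr_pmol_min", "phase"]


def read_ocr_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, _OCR_COLS, "OCR table", path)
    return df


def write_ocr_csv(traces, path) -> None:
    rows = []
    for tr in traces:
        for t, v, p in zip(tr.time_min, tr.ocr_pmol_min, tr.phase):
            row = {"well": tr.well, "time_min": t, "ocr_pmol_min": v,
                   "phase": p}
            if tr.protein_mg is not None:
                row["protein_mg"] = tr.protein_mg
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_panel_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "species"], "flux panel", path)
    return df


def write_panel_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Generic results writer; dialect chosen from the file suffix."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=index, float_format=FLOAT_FORMAT)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(vars(obj))
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True)
                          + "\n", encoding="utf-8")
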