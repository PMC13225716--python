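"""Readers and writers for the five input formats and the pipeline outputs.

All inputs are plain-text TSV/CSV with required headers:

* annotation TSV — columns ``gene``, ``term``
* curated list — one symbol per line, ``#`` comments allowed
* expression TSV — first column ``gene``, remaining columns cell lines (RPKM)
* edge-list TSV — columns ``protein1``, ``protein2``, plus one column per
  confidence channel (0-1 floats or the STRING 0-1000 integer convention)
* evidence CSV — columns ``gene``, ``knockdown_phenotype``,
  ``golgi_involvement``, optional ``citation``

Malformed headers or rows raise :class:`ParseError` carrying the 1-based
file line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from golgiscreen.evidence import KNOCKDOWN_PHENOTYPES, EvidenceRecord
from golgiscreen.rank import CandidateRecord
from golgiscreen.universe import normalize_symbol


class ParseError(ValueError):
    def __init__(self, path: str | Path, line: int | None, message: str) -> None:
        at = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{at}: {message}")
        self.path = str(path)
        self.line = line


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing required column(s): {', '.join(missing)}")


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["gene", "term"], path)
    df = df[["gene", "term"]].copy()
    df["gene"] = [normalize_symbol(g) for g in df["gene"].astype(str)]
    df["term"] = df["term"].astype(str).str.strip()
    return df.drop_duplicates(ignore_index=True)


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_curated(path: str | Path) -> list[str]:
    genes: list[str] = []
    seen: set[str] = set()
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            g = normalize_symbol(line)
        except ValueError as exc:
            raise ParseError(path, i, str(exc)) from exc
        if g not in seen:
            seen.add(g)
            genes.append(g)
    return genes


def write_curated(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene"], path)
    if df.columns[0] != "gene":
        raise ParseError(path, 1, "first column must be 'gene'")
    df["gene"] = [normalize_symbol(g) for g in df["gene"].astype(str)]
    dup = df["gene"].duplicated()
    if dup.any():
        i = int(dup.idxmax())
        raise ParseError(path, i + 2, f"duplicate gene symbol {df['gene'].iloc[i]!r}")
    df = df.set_index("gene")
    df = df.astype(float)
    neg = (df < 0).any(axis=1)
    if neg.any():
        pos = int(neg.to_numpy().argmax())
        raise ParseError(path, pos + 2, f"negative RPKM value for gene {df.index[pos]!r}")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("gene").to_csv(path, sep="\t")


def read_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["protein1", "protein2"], path)
    return df


def write_edges(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_evidence(path: str | Path) -> dict[str, EvidenceRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["gene", "knockdown_phenotype", "golgi_involvement"], path)
    records: dict[str, EvidenceRecord] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        gene = normalize_symbol(str(row.gene))
        phenotype = str(row.knockdown_phenotype).strip()
        if phenotype not in KNOCKDOWN_PHENOTYPES:
            raise ParseError(path, i + 2, f"unknown knockdown_phenotype {phenotype!r}")
        raw_inv = row.golgi_involvement
        if isinstance(raw_inv, str):
            token = raw_inv.strip().lower()
            if token not in ("true", "false"):
                raise ParseError(path, i + 2, f"golgi_involvement must be true/false, got {raw_inv!r}")
            involvement = token == "true"
        else:
            involvement = bool(raw_inv)
        records[gene] = EvidenceRecord(
            gene=gene, knockdown_phenotype=phenotype, golgi_involvement=involvement
        )
    return records


def write_evidence(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["golgi_involvement"] = out["golgi_involvement"].map({True: "true", False: "false"})
    out.to_csv(path, index=False)


def write_candidates(
    candidates: Mapping[str, Iterable[CandidateRecord]],
    common: set[str],
    parameters: Mapping[str, object],
    path: str | Path,
) -> None:
    """Candidate TSV across all cancer types with a provenance header line."""
    rows = []
    for cancer_type in sorted(candidates):
        for c in candidates[cancer_type]:
            rows.append(
                {
                    "cancer_type": cancer_type,
                    "rank": c.rank,
                    "gene": c.gene,
                    "fc": f"{c.fc:.6g}",
                    "direction": c.direction,
                    "score1": c.score1,
                    "score2": c.score2,
                    "combined": c.combined,
                    "common_to_both": str(c.gene in common).lower(),
                }
            )
    header = "# parameters: " + json.dumps(parameters, sort_keys=True) + "\n"
    body = pd.DataFrame(
        rows,
        columns=[
            "cancer_type", "rank", "gene", "fc", "direction",
            "score1", "score2", "combined", "common_to_both",
        ],
    ).to_csv(sep="\t", index=False)
    Path(path).write_text(header + body)


def write_report_json(report: Mapping[str, object], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
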