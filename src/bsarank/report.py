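"""Report rendering for score breakdowns, ranked tables and gap predictions.

JSON output is lossless (full precision plus provenance); TSV carries full
precision plus a printed-precision column; markdown is for human review.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from typing import Any, Iterable, Sequence

import pandas as pd

from .bcc import BccScoreBreakdown, display_score
from .bsa import BsaScoreBreakdown
from .relatedness import GapPrediction

__all__ = ["render_report", "breakdowns_to_frame", "gaps_to_frame", "overlap_to_frame"]


def breakdowns_to_frame(breakdowns: Sequence[BsaScoreBreakdown | BccScoreBreakdown]) -> pd.DataFrame:
    rows = []
    for b in breakdowns:
        row = b.to_dict()
        row.pop("provenance", None)
        score = row.get("total", row.get("bcc_score"))
        row["printed"] = display_score(score, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def gaps_to_frame(gaps: Iterable[GapPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug_id": g.drug_id,
                "virus_id": g.virus_id,
                "evidence_virus_id": g.evidence_virus_id,
                "relation": str(g.relation),
                "implied_c_phyl": g.implied_c_phyl,
            }
            for g in gaps
        ],
        columns=["drug_id", "virus_id", "evidence_virus_id", "relation", "implied_c_phyl"],
    )


def overlap_to_frame(counts: dict[frozenset[str], int]) -> pd.DataFrame:
    rows = [
        {"viruses": ";".join(sorted(subset)), "size": len(subset), "n_drugs": n}
        for subset, n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["viruses", "size", "n_drugs"]).sort_values(
        ["size", "viruses"], kind="mergesort"
    ).reset_index(drop=True)


def _to_records(results: Any) -> list[dict]:
    if isinstance(results, pd.DataFrame):
        return results.to_dict(orient="records")
    if is_dataclass(results) and not isinstance(results, type):
        results = [results]
    records = []
    for item in results:
        if hasattr(item, "to_dict"):
            records.append(item.to_dict())
        elif is_dataclass(item):
            records.append(asdict(item))
        elif isinstance(item, dict):
            records.append(item)
        else:
            raise TypeError(f"cannot render {type(item)!r}")
    return records


def _markdown_table(records: list[dict]) -> str:
    if not records:
        return "(empty)\n"
    cols = list(records[0].keys())
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for rec in records:
        lines.append("| " + " | ".join(str(rec.get(c, "")) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def render_report(results: Any, format: str = "json") -> str:
    """Render results (breakdowns, DataFrame, gap predictions) as a document.

    An empty result set renders as a valid empty document, never an error.
    """
    records = _to_records(results)
    if format == "json":
        return json.dumps(records, indent=2, default=str) + "\n"
    if format == "tsv":
        return pd.DataFrame(records).to_csv(sep="\t", index=False)
    if format == "markdown":
        return _markdown_table([{k: v for k, v in r.items() if k != "provenance"} for r in records])
    raise ValueError(f"unknown report format: {format!r}")
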