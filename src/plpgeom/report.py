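"""Rendering of per-protomer angle tables and state summaries.

TSV output rounds angles to one decimal and uses the literal ``n.a.`` for
absent values (the convention of crystallographic angle tables); JSON keeps
full precision with ``null`` for absent values. Both renderings are built
from the same rows, so they always contain identical numbers.
"""

from __future__ import annotations

import json

import pandas as pd

from .sites import DihedralReport, StateSummary

__all__ = ["reports_frame", "reports_tsv", "reports_json", "summary_tsv", "interface_tsv"]

_COLUMNS = ["structure", "protomer", "internal_deg", "external_deg", "state"]


def reports_frame(reports: list[DihedralReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.structure, r.protomer, r.internal_deg, r.external_deg, r.state) for r in reports],
        columns=_COLUMNS,
    )


def _fmt(v: float | None) -> str:
    return "n.a." if v is None else f"{v:.1f}"


def reports_tsv(reports: list[DihedralReport], summaries: list[StateSummary] | None = None) -> str:
    lines = ["\t".join(_COLUMNS)]
    for r in reports:
        lines.append("\t".join([r.structure, r.protomer, _fmt(r.internal_deg),
                                _fmt(r.external_deg), r.state]))
    if summaries:
        lines.append("")
        lines.append("\t".join(["state", "internal_mean", "internal_sd",
                                "external_mean", "external_sd", "n"]))
        for s in summaries:
            lines.append("\t".join([s.state, _fmt(s.mean_internal), _fmt(s.sd_internal),
                                    _fmt(s.mean_external), _fmt(s.sd_external), str(s.n)]))
    return "\n".join(lines) + "\n"


def reports_json(reports: list[DihedralReport], summaries: list[StateSummary] | None = None) -> str:
    payload: dict = {
        "protomers": [
            {"structure": r.structure, "protomer": r.protomer,
             "internal_deg": r.internal_deg, "external_deg": r.external_deg,
             "state": r.state}
            for r in reports
        ]
    }
    if summaries:
        payload["summary"] = [
            {"state": s.state, "internal_mean": s.mean_internal,
             "internal_sd": s.sd_internal, "external_mean": s.mean_external,
             "external_sd": s.sd_external, "n": s.n}
            for s in summaries
        ]
    return json.dumps(payload, indent=1) + "\n"


def summary_tsv(summaries: list[StateSummary]) -> str:
    return reports_tsv([], summaries).lstrip("\n")


def interface_tsv(report) -> str:
    lines = ["chain\tisolated_sasa_A2\tburied_A2"]
    for cid in report.buried_per_protomer:
        lines.append(f"{cid}\t{report.isolated_sasa_per_protomer[cid]:.1f}"
                     f"\t{report.buried_per_protomer[cid]:.1f}")
    return "\n".join(lines) + "\n"
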