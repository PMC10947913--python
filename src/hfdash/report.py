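"""Static HTML rendering of the KPI dashboard.

One self-contained page (inline CSS, no network): a score table per
reporting level with the national row on top for comparison,
green/yellow/red cell coloring, and per-KPI anchor links to the list
of actionable patients (those who fail the measure and whom a clinician
could act on).
"""

from __future__ import annotations

import html
from pathlib import Path

import pandas as pd

from .kpi import KpiConfig, KpiReport

__all__ = ["actionable_patients", "render_html", "write_html"]

_CSS = """
body { font-family: sans-serif; margin: 1.5em; }
table { border-collapse: collapse; margin-bottom: 1.5em; }
th, td { border: 1px solid #999; padding: 4px 10px; text-align: center; }
th { background: #eee; }
td.green { background: #c8e6c9; }
td.yellow { background: #fff9c4; }
td.red { background: #ffcdd2; }
td.none { background: #f5f5f5; color: #888; }
tr.national { font-weight: bold; }
.patients { font-family: monospace; font-size: 90%; }
"""


def actionable_patients(flags: pd.DataFrame, cfg: KpiConfig) -> dict[str, list[str]]:
    """Per KPI, the patients a clinician could act on.

    For a higher-is-better KPI these are denominator patients not yet
    meeting it; for a lower-is-better KPI, the patients flagged by it.
    """
    id_cols = {"patient_id", "provider_id", "facility_id", "network_id", "phenotype"}
    out: dict[str, list[str]] = {}
    for kpi in (c for c in flags.columns if c not in id_cols):
        col = flags[kpi]
        mask = col.notna()
        want = kpi in cfg.lower_is_better
        hits = flags.loc[mask & (col == want), "patient_id"]
        out[kpi] = sorted(hits.tolist())
    return out


def _fmt_cell(r: KpiReport) -> str:
    if r.percentage is None:
        return '<td class="none">&mdash;</td>'
    return (f'<td class="{r.color}">{r.percentage:.1f}%'
            f'<br><small>{r.numerator}/{r.denominator}</small></td>')


def render_html(reports: list[KpiReport],
                flags: pd.DataFrame,
                cfg: KpiConfig,
                title: str = "Heart Failure Dashboard") -> str:
    kpis = sorted({r.kpi for r in reports})
    by_unit: dict[tuple[str, str], dict[str, KpiReport]] = {}
    for r in reports:
        by_unit.setdefault((r.level, r.unit_id), {})[r.kpi] = r

    parts = [f"<!DOCTYPE html><html><head><meta charset='utf-8'>"
             f"<title>{html.escape(title)}</title><style>{_CSS}</style></head><body>"
             f"<h1>{html.escape(title)}</h1>"]
    if flags.empty:
        parts.append("<p><em>No patients in cohort.</em></p>")

    header = "<tr><th>Unit</th>" + "".join(
        f'<th><a href="#act-{k}">{html.escape(k)}</a></th>' for k in kpis) + "</tr>"
    for level in ("provider", "facility", "network"):
        units = sorted(u for (lv, u) in by_unit if lv == level)
        parts.append(f"<h2>By {level}</h2><table>{header}")
        national = by_unit.get(("national", "national"), {})
        cells = "".join(_fmt_cell(national[k]) if k in national
                        else '<td class="none">&mdash;</td>' for k in kpis)
        parts.append(f'<tr class="national"><td>National</td>{cells}</tr>')
        for unit in units:
            row = by_unit[(level, unit)]
            cells = "".join(_fmt_cell(row[k]) if k in row
                            else '<td class="none">&mdash;</td>' for k in kpis)
            parts.append(f"<tr><td>{html.escape(unit)}</td>{cells}</tr>")
        parts.append("</table>")

    parts.append("<h2>Actionable patients</h2>")
    for kpi, pids in actionable_patients(flags, cfg).items():
        listing = ", ".join(html.escape(p) for p in pids) if pids else "none"
        parts.append(f'<h3 id="act-{kpi}">{html.escape(kpi)}</h3>'
                     f'<p class="patients">{listing}</p>')
    parts.append("</body></html>")
    return "".join(parts)


def write_html(path: str | Path, *args, **kwargs) -> None:
    Path(path).write_text(render_html(*args, **kwargs), encoding="utf-8")
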