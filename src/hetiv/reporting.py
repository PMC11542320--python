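"""Stage 4: clinician-facing subgroup reports.

Clinical users of subgroup evidence asked for three complementary views:
everything in one forest plot ordered by effect size; main-effect rows
grouped by characteristic (age, sex, frailty, individual comorbidities) with
interaction rows indented beneath; and focal views restricted to a subgroup
of prime interest (e.g., patients aged 75 or older).  Every row shows the
numeric estimate, confidence interval, subgroup size and NES rate.  The
dynamic export is one self-contained HTML file (embedded data + vanilla JS)
so the report can be shared without a server.

No multiple-testing adjustment is applied by default: the subgroup estimates
are hypothesis-raising, and post hoc corrections such as Bonferroni can be
overly conservative; a flag applies the correction-style interval widening
for users who want it.
"""

from __future__ import annotations

import html
import json
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .liv import EffectEstimates

ROW_COLUMNS = [
    "label", "term", "estimate", "ci_low", "ci_high", "n", "nes_share",
    "group_key", "indent_level",
]


@dataclass
class ForestSpec:
    """Renderable forest-plot rows with ordering and filter state."""

    rows: pd.DataFrame  # ROW_COLUMNS
    ordering: str = "effect"
    filters: dict = field(default_factory=dict)
    show_values: bool = True
    show_n: bool = True
    show_rates: bool = True
    title: str = "Comparative effectiveness by subgroup (DAOH at 90 days)"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "ordering": self.ordering,
                    "filters": {k: str(v) for k, v in self.filters.items()},
                    "rows": self.rows.to_dict(orient="records"),
                },
                fh,
                indent=2,
                default=float,
            )


def _group_key(term: str) -> str:
    if term in ("age_band", "sex", "frailty"):
        return term
    return term.split(":")[0]


def build_forest(
    effects: EffectEstimates,
    ordering: str = "effect",
    filters: dict | None = None,
    custom_order: list[str] | None = None,
    include_overall: bool = True,
    show_values: bool = True,
    show_n: bool = True,
    show_rates: bool = True,
) -> ForestSpec:
    """Assemble forest-plot rows from subgroup estimates.

    ordering: "effect" (nonincreasing estimate), "group" (rows grouped by
    characteristic, interaction rows indented under their first parent), or
    "custom" (by ``custom_order`` labels).  ``filters`` maps a name to either
    a predicate over the row (callable) or a term substring that the row's
    defining term must contain; rows failing any filter are removed.  Ties in
    ordering are broken lexicographically by label.
    """
    if ordering not in ("effect", "group", "custom"):
        raise ValueError("ordering must be 'effect', 'group' or 'custom'")
    tab = effects.table.copy()
    tab["group_key"] = [_group_key(t) for t in tab["term"]]
    tab["indent_level"] = [1 if ":" in t else 0 for t in tab["term"]]

    if filters:
        keep = np.ones(len(tab), dtype=bool)
        for name, f in filters.items():
            if callable(f):
                keep &= tab.apply(f, axis=1).to_numpy(bool)
            else:
                keep &= tab["term"].str.contains(str(f), regex=False).to_numpy()
        tab = tab[keep]
        if tab.empty:
            warnings.warn("filters matched no subgroup rows", stacklevel=2)

    if ordering == "effect":
        tab = tab.sort_values(
            ["estimate", "label"], ascending=[False, True], kind="mergesort"
        )
    elif ordering == "group":
        tab = tab.sort_values(
            ["group_key", "indent_level", "label"], kind="mergesort"
        )
    else:
        order = {lb: i for i, lb in enumerate(custom_order or [])}
        tab = tab.sort_values(
            ["label"], kind="mergesort"
        ).sort_values(
            by="label", key=lambda s: s.map(lambda lb: order.get(lb, len(order))),
            kind="mergesort",
        )

    if include_overall:
        ov = pd.DataFrame(
            [
                {
                    "label": "overall",
                    "term": "overall",
                    "estimate": effects.overall["estimate"],
                    "ci_low": effects.overall["ci_low"],
                    "ci_high": effects.overall["ci_high"],
                    "n": effects.overall["n"],
                    "nes_share": effects.overall["nes_share"],
                    "group_key": "overall",
                    "indent_level": 0,
                }
            ]
        )
        tab = pd.concat([ov, tab], ignore_index=True)
    return ForestSpec(
        rows=tab[ROW_COLUMNS].reset_index(drop=True),
        ordering=ordering,
        filters=filters or {},
        show_values=show_values,
        show_n=show_n,
        show_rates=show_rates,
    )


def adjust_intervals(spec: ForestSpec, method: str = "bonferroni") -> ForestSpec:
    """Optional conservative widening of the intervals for multiplicity.

    Rescales each interval's half-widths as if the underlying normal quantile
    moved from 1 - alpha/2 to 1 - alpha/(2m) for m reported subgroups.  OFF by
    default everywhere else in the package.
    """
    if method != "bonferroni":
        raise ValueError("only the Bonferroni-style widening is provided")
    rows = spec.rows.copy()
    m = max((rows["term"] != "overall").sum(), 1)
    z0 = stats.norm.ppf(0.975)
    zm = stats.norm.ppf(1 - 0.025 / m)
    scale = zm / z0
    for side, sign in (("ci_low", -1), ("ci_high", 1)):
        rows[side] = rows["estimate"] + scale * (rows[side] - rows["estimate"])
    out = ForestSpec(
        rows=rows, ordering=spec.ordering, filters=dict(spec.filters),
        show_values=spec.show_values, show_n=spec.show_n,
        show_rates=spec.show_rates, title=spec.title + " (Bonferroni-widened)",
    )
    return out


def _atomic_write(path: str, data: bytes) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def render_forest(spec: ForestSpec, path: str, format: str = "static") -> str:
    """Write the forest plot: static PNG/SVG or self-contained dynamic HTML.

    The dynamic export embeds the row data as JSON inside the HTML, so a
    round trip (parse the file, read the JSON) recovers the exact row set.
    Files are written atomically.  An empty spec yields a placeholder with a
    "no subgroups" notice and succeeds.
    """
    if format == "static":
        _render_static(spec, path)
    elif format == "dynamic":
        _atomic_write(path, _dynamic_html(spec).encode())
    else:
        raise ValueError("format must be 'static' or 'dynamic'")
    return path


def _render_static(spec: ForestSpec, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = spec.rows
    n = len(rows)
    fig, ax = plt.subplots(figsize=(9, max(2.5, 0.32 * n + 1.5)))
    if n == 0:
        ax.text(0.5, 0.5, "no subgroups", ha="center", va="center")
        ax.set_axis_off()
    else:
        ypos = np.arange(n)[::-1]
        est = rows["estimate"].to_numpy(float)
        lo = rows["ci_low"].to_numpy(float)
        hi = rows["ci_high"].to_numpy(float)
        err = np.vstack([est - lo, hi - est])
        err = np.where(np.isfinite(err), err, 0.0)
        ax.errorbar(est, ypos, xerr=err, fmt="o", color="k", ecolor="gray",
                    capsize=2, markersize=4)
        labels = []
        for _, r in rows.iterrows():
            lab = "  " * int(r["indent_level"]) + str(r["label"])
            extra = []
            if spec.show_values:
                ci = (
                    f" ({r['ci_low']:.1f}, {r['ci_high']:.1f})"
                    if np.isfinite(r["ci_low"])
                    else ""
                )
                extra.append(f"{r['estimate']:.1f}{ci}")
            if spec.show_n:
                extra.append(f"n={int(r['n'])}")
            if spec.show_rates and np.isfinite(r["nes_share"]):
                extra.append(f"NES {100 * r['nes_share']:.0f}%")
            labels.append(lab + ("  [" + ", ".join(extra) + "]" if extra else ""))
        ax.set_yticks(ypos)
        ax.set_yticklabels(labels, fontsize=7)
        ax.axvline(0.0, color="firebrick", lw=0.8, ls="--")
        ax.set_xlabel("effect of NES vs ES on DAOH at 90 days")
        ax.set_title(spec.title, fontsize=10)
    fig.tight_layout()
    import io

    buf = io.BytesIO()
    fig.savefig(buf, format=os.path.splitext(path)[1].lstrip(".") or "png",
                dpi=150)
    plt.close(fig)
    _atomic_write(path, buf.getvalue())


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 1.5em; }}
table {{ border-collapse: collapse; }}
td, th {{ padding: 2px 8px; font-size: 13px; text-align: left; }}
tr:nth-child(even) {{ background: #f4f4f4; }}
.bar {{ height: 14px; position: relative; width: 320px; }}
.ci {{ position: absolute; height: 2px; top: 6px; background: #888; }}
.pt {{ position: absolute; width: 6px; height: 6px; top: 4px;
      background: #222; border-radius: 3px; }}
.zero {{ position: absolute; width: 1px; height: 14px; background: #c33; }}
.indent1 {{ padding-left: 1.6em; }}
</style></head>
<body>
<h2>{title}</h2>
<p>Rows are subgroup estimates of the effect of NES strategies vs ES on days
alive and out of hospital (DAOH) at 90 days, with percentile bootstrap
intervals, subgroup sizes and NES rates.</p>
<label>Order: <select id="order">
<option value="effect">by effect size</option>
<option value="group">by grouping</option>
<option value="label">by label</option>
</select></label>
<label> Filter term: <input id="filter" type="text" placeholder="e.g. age"/></label>
<table id="forest"><thead><tr>
<th>subgroup</th><th>effect (95% CI)</th><th></th><th>n</th><th>NES %</th>
</tr></thead><tbody></tbody></table>
<script id="forest-data" type="application/json">{data}</script>
<script>
const rows = JSON.parse(document.getElementById('forest-data').textContent).rows;
const lo = Math.min(0, ...rows.map(r => r.ci_low).filter(Number.isFinite),
                    ...rows.map(r => r.estimate));
const hi = Math.max(0, ...rows.map(r => r.ci_high).filter(Number.isFinite),
                    ...rows.map(r => r.estimate));
const px = v => 320 * (v - lo) / (hi - lo || 1);
function draw() {{
  const ord = document.getElementById('order').value;
  const flt = document.getElementById('filter').value.toLowerCase();
  let shown = rows.filter(r => !flt || r.term.toLowerCase().includes(flt)
                          || r.label.toLowerCase().includes(flt));
  if (ord === 'effect') shown.sort((a, b) => b.estimate - a.estimate);
  else if (ord === 'group') shown.sort((a, b) =>
    (a.group_key + a.indent_level + a.label)
      .localeCompare(b.group_key + b.indent_level + b.label));
  else shown.sort((a, b) => a.label.localeCompare(b.label));
  const body = document.querySelector('#forest tbody');
  body.innerHTML = '';
  for (const r of shown) {{
    const tr = document.createElement('tr');
    const ci = Number.isFinite(r.ci_low)
      ? ` (${{r.ci_low.toFixed(1)}}, ${{r.ci_high.toFixed(1)}})` : '';
    const bar = Number.isFinite(r.ci_low)
      ? `<div class="ci" style="left:${{px(r.ci_low)}}px;` +
        `width:${{Math.max(px(r.ci_high) - px(r.ci_low), 1)}}px"></div>` : '';
    tr.innerHTML =
      `<td class="indent${{r.indent_level}}">${{r.label}}</td>` +
      `<td>${{r.estimate.toFixed(1)}}${{ci}}</td>` +
      `<td><div class="bar">${{bar}}` +
      `<div class="pt" style="left:${{px(r.estimate) - 3}}px"></div>` +
      `<div class="zero" style="left:${{px(0)}}px"></div></div></td>` +
      `<td>${{r.n}}</td><td>${{(100 * r.nes_share).toFixed(0)}}</td>`;
    body.appendChild(tr);
  }}
  if (!shown.length) body.innerHTML = '<tr><td colspan="5">no subgroups</td></tr>';
}}
document.getElementById('order').addEventListener('change', draw);
document.getElementById('filter').addEventListener('input', draw);
draw();
</script></body></html>
"""


def _dynamic_html(spec: ForestSpec) -> str:
    payload = {
        "ordering": spec.ordering,
        "rows": json.loads(
            spec.rows.to_json(orient="records", double_precision=12)
        ),
    }
    return _HTML_TEMPLATE.format(
        title=html.escape(spec.title),
        data=json.dumps(payload),
    )


def read_dynamic_rows(path: str) -> pd.DataFrame:
    """Recover the row set embedded in a dynamic HTML export."""
    with open(path) as fh:
        text = fh.read()
    marker = '<script id="forest-data" type="application/json">'
    start = text.index(marker) + len(marker)
    end = text.index("</script>", start)
    payload = json.loads(text[start:end])
    return pd.DataFrame(payload["rows"])
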