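"""Interactive sample-selection report and stage-progress accounting.

The selection report is one self-contained HTML file (inline style and
script, no server) with collapsible family and genus levels, a text
filter, and per-sample status glyphs whose meaning appears on hover — the
tool the team uses to prioritise sequencing. A companion CSV mirrors the
species-level rows exactly; both derive from the same intermediate table,
which the HTML also embeds as JSON so the two can be compared
mechanically.
"""

from __future__ import annotations

import html as _html
import json
from pathlib import Path

import pandas as pd

from .datastore import ProjectDB

GLYPHS = [
    ("sampled", "&#9679;", "tissue sampled (sampling event recorded)"),
    ("imaged", "&#128247;", "specimen photograph linked"),
    ("extracted", "&#9724;", "assigned to an extraction well"),
    ("yield_ok", "&#10003;", "total DNA at or above the 10 ng floor"),
    ("submitted", "&#9992;", "included on a submission plate"),
    ("sequenced_ok", "&#9733;", "sequence data returned"),
    ("rejected_low_yield", "&#10007;", "rejected: yield below 10 ng"),
    ("failed_qc", "&#9888;", "sequencing failure (<5% of loci recovered)"),
]
STAGE_COLUMNS = [g[0] for g in GLYPHS]


def species_table(db: ProjectDB) -> pd.DataFrame:
    """One row per sample with family/genus/species context and the glyph
    booleans; deterministic order (family, genus, species, uuid)."""
    q = """
    SELECT t.family, t.accepted_name, l.sample_uuid
    FROM taxon_sample_links l JOIN taxa t ON t.taxon_id = l.taxon_id
    """
    rows = []
    imaged = {r[0] for r in db.conn.execute(
        "SELECT DISTINCT sample_uuid FROM images WHERE sample_uuid"
        " IS NOT NULL")}
    extracted = {r[0] for r in db.conn.execute(
        "SELECT DISTINCT sample_uuid FROM extraction_wells WHERE"
        " sample_uuid IS NOT NULL")}
    yields = {r[0]: r[1] for r in db.conn.execute(
        "SELECT sample_uuid, total_dna_ng FROM yields")}
    submitted = {r[0] for r in db.conn.execute(
        "SELECT sample_uuid FROM sequencing_wells WHERE decision ="
        " 'included'")}
    sequenced = {r[0] for r in db.conn.execute(
        "SELECT DISTINCT sample_uuid FROM locus_recovery")}
    failed = {r[0] for r in db.conn.execute(
        "SELECT sample_uuid FROM qc_summary WHERE failed = 1")}
    ymin = db.config.yield_min_ng
    for fam, name, uuid in db.conn.execute(q):
        genus = name.split()[0]
        has_yield = uuid in yields
        rows.append({
            "family": fam, "genus": genus, "species": name,
            "sample_uuid": uuid,
            "sampled": True,
            "imaged": uuid in imaged,
            "extracted": uuid in extracted,
            "yield_ok": has_yield and yields[uuid] >= ymin,
            "submitted": uuid in submitted,
            "sequenced_ok": uuid in sequenced,
            "rejected_low_yield": has_yield and yields[uuid] < ymin,
            "failed_qc": uuid in failed,
        })
    df = pd.DataFrame(rows, columns=["family", "genus", "species",
                                     "sample_uuid"] + STAGE_COLUMNS)
    return df.sort_values(["family", "genus", "species", "sample_uuid"]
                          ).reset_index(drop=True)


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Sample selection report</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
details {{ margin-left: 1em; }}
table {{ border-collapse: collapse; margin-left: 2em; }}
td, th {{ padding: 1px 8px; font-size: 13px; text-align: left; }}
.glyph {{ cursor: help; }}
.count {{ color: #666; font-size: 12px; }}
#legend span {{ margin-right: 1.2em; }}
</style></head><body>
<h1>Sample selection report</h1>
<p id="legend">{legend}</p>
<input id="filter" placeholder="filter by family / genus / species"
 oninput="applyFilter(this.value)" size="40">
{body}
<script id="species-data" type="application/json">{data_json}</script>
<script>
function applyFilter(q) {{
  q = q.toLowerCase();
  document.querySelectorAll('tr.species-row').forEach(function (tr) {{
    tr.style.display = tr.dataset.key.includes(q) ? '' : 'none';
  }});
  document.querySelectorAll('details').forEach(function (d) {{
    if (q) d.open = true;
  }});
}}
</script>
</body></html>
"""


def _glyph_cells(rec: dict) -> str:
    cells = []
    for key, symbol, tip in GLYPHS:
        mark = symbol if rec[key] else "&middot;"
        cells.append(f'<td class="glyph" title="{tip}">{mark}</td>')
    return "".join(cells)


def build_selection_report(db: ProjectDB, out_dir: str | Path,
                           ) -> tuple[Path, Path]:
    """Write sample_selection.html + sample_selection.csv; returns both
    paths. An empty database yields a valid report with zero rows."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = species_table(db)
    csv_path = out_dir / "sample_selection.csv"
    df.to_csv(csv_path, index=False)

    parts = []
    for family, fam_df in df.groupby("family", sort=True):
        fam_counts = ", ".join(
            f"{k}: {int(fam_df[k].sum())}" for k in STAGE_COLUMNS
            if fam_df[k].any())
        parts.append(f"<details><summary><b>{_html.escape(str(family))}</b>"
                     f" <span class='count'>({len(fam_df)} samples;"
                     f" {fam_counts})</span></summary>")
        for genus, gen_df in fam_df.groupby("genus", sort=True):
            parts.append(
                f"<details><summary><i>{_html.escape(str(genus))}</i>"
                f" <span class='count'>({len(gen_df)} samples)</span>"
                "</summary><table>")
            header = "".join(f"<th title='{tip}'>{sym}</th>"
                             for _, sym, tip in GLYPHS)
            parts.append(f"<tr><th>species</th><th>sample</th>{header}</tr>")
            for rec in gen_df.to_dict("records"):
                key = _html.escape(
                    f"{rec['family']} {rec['genus']} {rec['species']}".lower())
                parts.append(
                    f'<tr class="species-row" data-key="{key}">'
                    f"<td><i>{_html.escape(rec['species'])}</i></td>"
                    f"<td><code>{rec['sample_uuid']}</code></td>"
                    f"{_glyph_cells(rec)}</tr>")
            parts.append("</table></details>")
        parts.append("</details>")

    legend = " ".join(
        f'<span class="glyph" title="{tip}">{sym}&nbsp;{key}</span>'
        for key, sym, tip in GLYPHS)
    data_json = json.dumps(df.to_dict("records"), default=bool)
    html_path = out_dir / "sample_selection.html"
    html_path.write_text(_PAGE.format(
        legend=legend, body="\n".join(parts), data_json=data_json))
    return html_path, csv_path


def parse_report_species_rows(html_path: str | Path) -> pd.DataFrame:
    """Recover the species-level rows embedded in a report (the JSON block
    the page itself renders from)."""
    text = Path(html_path).read_text()
    start = text.index('<script id="species-data" type="application/json">')
    start = text.index(">", start) + 1
    end = text.index("</script>", start)
    records = json.loads(text[start:end])
    df = pd.DataFrame(records, columns=["family", "genus", "species",
                                        "sample_uuid"] + STAGE_COLUMNS)
    return df


STAGES = ["sampled", "imaged", "extracted", "quantified", "submitted",
          "sequenced", "qc_passed"]


def progress_report(db: ProjectDB) -> pd.DataFrame:
    """Samples surviving each workflow stage, in pipeline order.

    Counts are cumulative (a sample counts at a stage only if it also
    passed every earlier stage), so they are monotone non-increasing.
    """
    def uuids(sql: str) -> set[str]:
        return {r[0] for r in db.conn.execute(sql)}

    stage_sets = [
        uuids("SELECT DISTINCT sample_uuid FROM sampling_events"),
        uuids("SELECT DISTINCT sample_uuid FROM images WHERE sample_uuid"
              " IS NOT NULL"),
        uuids("SELECT DISTINCT sample_uuid FROM extraction_wells WHERE"
              " sample_uuid IS NOT NULL"),
        uuids("SELECT sample_uuid FROM yields"),
        uuids("SELECT sample_uuid FROM sequencing_wells WHERE decision ="
              " 'included'"),
        uuids("SELECT DISTINCT sample_uuid FROM locus_recovery"),
        uuids("SELECT sample_uuid FROM qc_summary WHERE failed = 0"),
    ]
    rows = []
    survivors: set[str] | None = None
    for stage, members in zip(STAGES, stage_sets):
        survivors = members if survivors is None else survivors & members
        rows.append({"stage": stage, "n_samples": len(survivors)})
    return pd.DataFrame(rows)
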