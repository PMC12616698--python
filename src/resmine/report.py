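"""Report rendering: schema-versioned JSON and a self-contained HTML page.

The JSON report is the canonical, lossless serialization of a run (it
round-trips through ``json.load`` unchanged and is byte-deterministic for
identical inputs). The HTML page shows per-family cards with gene arrow
diagrams and hook annotations for human browsing.
"""

from __future__ import annotations

import html
import json
from types import SimpleNamespace

SUPPORTED_FORMATS = ("json", "html")


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def render_report(report: dict, fmt: str, path) -> None:
    """Render a report dict to ``path`` as 'json' or 'html'."""
    if fmt == "json":
        report_to_json(report, path)
    elif fmt == "html":
        report_to_html(report, path)
    else:
        raise ValueError(
            f"unknown format {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )


def _gene_arrow_svg(region: dict) -> str:
    genes = region["genes"]
    if not genes:
        return ""
    lo = min(g["start"] for g in genes)
    hi = max(g["end"] for g in genes)
    span = max(hi - lo, 1)
    width = 640
    parts = [
        f'<svg width="{width}" height="36" '
        f'xmlns="http://www.w3.org/2000/svg">'
    ]
    cores = region.get("core_classes", {})
    hook_genes = {h["gene_id"] for h in region.get("hooks", [])}
    for g in genes:
        x0 = 10 + (g["start"] - lo) / span * (width - 20)
        x1 = 10 + (g["end"] - lo) / span * (width - 20)
        w = max(x1 - x0, 4)
        if g["gene_id"] in cores:
            color = "#d62728"
        elif g["gene_id"] in hook_genes:
            color = "#1f77b4"
        else:
            color = "#aaaaaa"
        head = 6 if w > 10 else w / 2
        if g["strand"] == "+":
            points = (
                f"{x0},10 {x1 - head},10 {x1},18 {x1 - head},26 {x0},26"
            )
        else:
            points = (
                f"{x1},10 {x0 + head},10 {x0},18 {x0 + head},26 {x1},26"
            )
        title = html.escape(f"{g['gene_id']} {g.get('product', '')}".strip())
        parts.append(
            f'<polygon points="{points}" fill="{color}">'
            f"<title>{title}</title></polygon>"
        )
    parts.append("</svg>")
    return "".join(parts)


def report_to_html(report: dict, path) -> None:
    regions_by_id = {r["region_id"]: r for r in report.get("regions", [])}
    annotations = report.get("hook_annotations", {})
    families = report.get("families", [])
    blocks = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>resmine report</title>"
        "<style>body{font-family:sans-serif;margin:2em}"
        ".card{border:1px solid #ccc;border-radius:6px;padding:1em;"
        "margin:1em 0}.meta{color:#555;font-size:0.9em}</style></head><body>",
        "<h1>Resistance-gene-guided mining report</h1>",
        f"<p class='meta'>resmine {html.escape(str(report['provenance']['version']))}"
        f" &mdash; {len(report.get('genomes', []))} genomes, "
        f"{report.get('n_flagged', 0)} flagged regions, "
        f"{len(families)} families after filtering.</p>",
    ]
    for notice in report.get("notices", []):
        blocks.append(f"<p class='meta'>note: {html.escape(notice)}</p>")
    if not families:
        blocks.append("<p><strong>No gene-cluster families to show.</strong></p>")
    for fam in families:
        hook = fam.get("hook_id") or "none"
        ann = annotations.get(hook, "")
        blocks.append("<div class='card'>")
        blocks.append(
            f"<h2>{html.escape(fam['family_id'])}</h2>"
            f"<p>hook: <strong>{html.escape(hook)}</strong>"
            + (f" &mdash; {html.escape(ann)}" if ann else "")
            + f"<br>cores: {html.escape(', '.join(fam.get('core_signature', [])))}"
            f"<br>genera: {html.escape(', '.join(fam.get('genera', [])))}</p>"
        )
        for rid in fam["members"]:
            region = regions_by_id.get(rid)
            if region is None:
                continue
            blocks.append(
                f"<p class='meta'>{html.escape(rid)} "
                f"({html.escape(region['genus'])}, "
                f"{region['end'] - region['start']} bp, "
                f"{len(region['genes'])} genes)</p>"
            )
            blocks.append(_gene_arrow_svg(region))
        blocks.append("</div>")
    blocks.append("</body></html>")
    with open(path, "w") as fh:
        fh.write("\n".join(blocks))


def regions_from_report(report: dict) -> list:
    """Lightweight region stand-ins reconstructed from a report dict.

    They expose the attributes evaluation and family bookkeeping need
    (region_id, assembly_id, contig_id, interval, genes, flagged, genus,
    taxonomic_class, core_class_multiset(), best_hook()).
    """
    out = []
    for r in report.get("regions", []):
        hooks = r.get("hooks", [])
        best = max(hooks, key=lambda h: h["percent_identity"], default=None)
        shim = SimpleNamespace(
            region_id=r["region_id"],
            assembly_id=r["assembly_id"],
            contig_id=r["contig"],
            interval=(r["start"], r["end"]),
            genes=[g["gene_id"] for g in r["genes"]],
            flagged=r["flagged"],
            genus=r["genus"],
            taxonomic_class=r["taxonomic_class"],
        )
        classes = tuple(sorted(r.get("core_classes", {}).values()))
        shim.core_class_multiset = lambda classes=classes: classes
        bh = (
            SimpleNamespace(hook_id=best["hook_id"],
                            outside_copies=best["outside_copies"])
            if best
            else None
        )
        shim.best_hook = lambda bh=bh: bh
        out.append(shim)
    return out


def families_from_report(report: dict, key: str = "families") -> list:
    """Family stand-ins (family_id + members as region shims) from a report."""
    regions = {s.region_id: s for s in regions_from_report(report)}
    fams = []
    for f in report.get(key, []):
        fams.append(
            SimpleNamespace(
                family_id=f["family_id"],
                members=[regions[rid] for rid in f["members"]],
                hook_signature=f.get("hook_id"),
                core_signature=tuple(f.get("core_signature", [])),
                genera=set(f.get("genera", [])),
                class_counts=dict(f.get("class_counts", {})),
            )
        )
    return fams
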