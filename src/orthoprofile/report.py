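"""HTML rendering of the profile matrix (the clickable coloured-box display).

One column per genome, coloured by taxon group; grey boxes are reciprocal
hits below the orthology criteria, white boxes mean no reciprocal hit, and a
"T" marks orthologues whose target gene carries an in-frame TTA codon.
Tooltips carry the gene identifier, percentage identity and overlap length.
Rendered with plain string formatting; the output is self-contained HTML.
"""

from __future__ import annotations

from pathlib import Path

from .genome_io import GenomeRegistry
from .orthology import ABSENT, ORTHOLOGUE, ProfileMatrix

__all__ = ["render_report"]

# qualitative palette for taxon groups, recycled if there are more groups
_GROUP_COLOURS = [
    "#4f81bd", "#9bbb59", "#c0504d", "#8064a2",
    "#f79646", "#4bacc6", "#b8a066", "#7f9fbf",
]

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>ortholog profile</title>
<style>
table {{ border-collapse: collapse; font: 11px sans-serif; }}
th {{ padding: 2px 4px; }} th.group {{ color: #fff; }}
td.cell {{ width: 18px; height: 16px; text-align: center; border: 1px solid #ddd;
          font-weight: bold; cursor: default; }}
td.sub {{ background: #bfbfbf !important; }}
td.absent {{ background: #ffffff !important; }}
th.gene {{ text-align: right; font-weight: normal; }}
th.gene.tta {{ background: #ffe680; }}
</style></head><body>
<h2>Reciprocal-best-hit ortholog profile (reference: {reference})</h2>
<p>Coloured box: orthologue (colour = taxon group); grey: reciprocal hit
below the orthology criteria; white: no reciprocal hit; T: TTA codon in the
target gene; yellow row label: TTA codon in the reference gene.</p>
<table>
{header}
{rows}
</table></body></html>
"""


def render_report(
    matrix: ProfileMatrix,
    registry: GenomeRegistry,
    out_path: str | Path | None = None,
) -> str:
    """Render the matrix as an HTML heatmap; optionally write it to a file.

    Raises ``ValueError`` if the matrix and registry do not describe the
    same genomes.
    """
    missing = [g for g in matrix.genome_ids if g not in registry.genomes]
    if missing:
        raise ValueError(f"report: genomes missing from registry: {missing}")

    colour_of = {
        grp: _GROUP_COLOURS[i % len(_GROUP_COLOURS)]
        for i, grp in enumerate(registry.group_order)
    }
    header_cells = ["<th></th>"]
    for gid in matrix.genome_ids:
        grp = registry.genomes[gid].taxon_group
        header_cells.append(
            f'<th class="group" style="background:{colour_of.get(grp, "#888")}"'
            f' title="{grp}">{gid}</th>'
        )
    header = "<tr>" + "".join(header_cells) + "</tr>"

    ref = registry.reference
    rows = []
    for gene_id in matrix.gene_ids:
        ref_tta = ""
        try:
            from .codon_tta import scan_tta

            g = ref.get(gene_id)
            if len(g.cds) >= 3 and scan_tta(g.cds).has_tta:
                ref_tta = " tta"
        except KeyError:
            pass
        cells = [f'<th class="gene{ref_tta}">{gene_id}</th>']
        for gid in matrix.genome_ids:
            call = matrix.call(gene_id, gid)
            grp = registry.genomes[gid].taxon_group
            if call.status == ABSENT:
                cells.append(
                    f'<td class="cell absent" title="{gene_id} / {gid}: '
                    f'no reciprocal hit"></td>'
                )
                continue
            aln = call.alignment
            tip = (
                f"{gene_id} -> {call.target_gene_id} ({gid}): "
                f"identity {aln.identity_pct:.1f}%, overlap {aln.overlap}"
            )
            marker = "T" if call.tta_in_target else ""
            if call.status == ORTHOLOGUE:
                cells.append(
                    f'<td class="cell" style="background:'
                    f'{colour_of.get(grp, "#888")}" title="{tip}">{marker}</td>'
                )
            else:
                cells.append(f'<td class="cell sub" title="{tip}">{marker}</td>')
        rows.append("<tr>" + "".join(cells) + "</tr>")

    html = _PAGE.format(
        reference=matrix.reference_id, header=header, rows="\n".join(rows)
    )
    if out_path is not None:
        Path(out_path).write_text(html)
    return html
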