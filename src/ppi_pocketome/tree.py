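"""The pocketome as a minimum spanning tree over pocket similarity.

Every pocket is a node; the tree keeps the N-1 edges that connect the
whole collection while minimising the total descriptor-space distance.
Because the PSI kernel is strictly decreasing in distance, the
minimum-distance tree is also the maximum-similarity tree.  Nodes carry
annotations (pocket class/subset, volume, exposure, Pfam/CATH fields) for
colour-coded exploration; trees export to GraphML or to a self-contained
interactive HTML page.

*Exposure* is a toolkit definition: the fraction of cavity grid points
with buriedness at or below 60 — there is no community-standard formula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .models import Cavity
from .psi import DistanceMatrix, psi

__all__ = [
    "PocketomeTree",
    "minimum_spanning_tree",
    "annotate_tree",
    "exposure",
    "branch_homogeneity",
    "export_tree",
    "read_graphml",
]

EXPOSURE_BURIEDNESS = 60

#: Annotation fields attached to every node (missing values become "NA").
ANNOTATION_FIELDS = ("subset", "volume", "exposure", "pfam_name",
                     "pfam_accession", "cath_name", "cath_class",
                     "architecture", "topology")


@dataclass
class PocketomeTree:
    """A spanning tree over pockets with per-node annotations."""

    graph: nx.Graph

    @property
    def total_weight(self) -> float:
        return float(sum(d["distance"] for _, _, d in self.graph.edges(data=True)))

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def minimum_spanning_tree(dist: DistanceMatrix) -> PocketomeTree:
    """Exact MST over the full distance matrix (Kruskal).

    Edges are inserted in lexicographic pocket-ID order so that equal
    weights break ties deterministically.  Every edge stores both its
    distance and the PSI value at the matrix's sigma.
    """
    n = len(dist)
    if n < 2:
        raise ValueError("need at least 2 pockets")
    if not np.all(np.isfinite(dist.d)):
        raise ValueError("non-finite distances")
    g = nx.Graph()
    order = sorted(range(n), key=lambda i: dist.pocket_ids[i])
    g.add_nodes_from(dist.pocket_ids[i] for i in order)
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1:]:
            g.add_edge(dist.pocket_ids[i], dist.pocket_ids[j],
                       distance=float(dist.d[i, j]),
                       psi=float(psi(dist.d[i, j], dist.sigma)))
    mst = nx.minimum_spanning_tree(g, weight="distance", algorithm="kruskal")
    return PocketomeTree(graph=mst)


def exposure(cavity: Cavity) -> float:
    """Fraction of cavity points with buriedness <= 60 (toolkit definition)."""
    if len(cavity) == 0:
        raise ValueError("empty cavity")
    b = cavity.buriedness_values()
    return float(np.mean(b <= EXPOSURE_BURIEDNESS))


def annotate_tree(
    tree: PocketomeTree,
    annotations: pd.DataFrame | Mapping[str, Mapping],
    allow_missing: bool = False,
) -> PocketomeTree:
    """Attach annotation fields to every node (in place).

    *annotations* maps pocket ID to a field dictionary (or is a DataFrame
    indexed by pocket ID).  Unknown nodes raise unless *allow_missing*, in
    which case their fields read "NA".
    """
    if isinstance(annotations, pd.DataFrame):
        if annotations.index.has_duplicates:
            raise ValueError("duplicate pocket IDs in annotation table")
        table = {str(idx): row.to_dict() for idx, row in annotations.iterrows()}
    else:
        table = {str(k): dict(v) for k, v in annotations.items()}

    for node in tree.graph.nodes:
        if node not in table:
            if not allow_missing:
                raise KeyError(f"no annotation for pocket {node!r}")
            record = {}
        else:
            record = table[node]
        for fieldname in ANNOTATION_FIELDS:
            value = record.get(fieldname, "NA")
            if value is None or (isinstance(value, float) and np.isnan(value)):
                value = "NA"
            tree.graph.nodes[node][fieldname] = value
        for fieldname, value in record.items():
            if fieldname not in ANNOTATION_FIELDS:
                tree.graph.nodes[node][fieldname] = value
    return tree


def branch_homogeneity(tree: PocketomeTree, label_field: str) -> float:
    """Fraction of edges whose endpoints share the label (NA excluded)."""
    same = total = 0
    for u, v in tree.graph.edges:
        try:
            lu = tree.graph.nodes[u][label_field]
            lv = tree.graph.nodes[v][label_field]
        except KeyError:
            raise KeyError(f"label field {label_field!r} missing on nodes") from None
        if lu == "NA" or lv == "NA":
            continue
        total += 1
        same += int(lu == lv)
    if total == 0:
        raise ValueError(f"no labelled edges for field {label_field!r}")
    return same / total


# ---------------------------------------------------------------------------
# export


_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Pocketome tree</title>
<style>
 body {{ font-family: sans-serif; margin: 0; }}
 #bar {{ padding: 6px; background: #eee; }}
 svg {{ width: 100vw; height: 92vh; }}
 circle {{ stroke: #333; stroke-width: 0.5; }}
 line {{ stroke: #999; stroke-width: 1; }}
 text.tip {{ font-size: 10px; }}
</style>
</head>
<body>
<div id="bar">Colour by:
<select id="prop">{options}</select>
<span id="legend"></span></div>
<svg id="view"></svg>
<script>
const data = {data};
const svg = document.getElementById('view');
const W = window.innerWidth, H = window.innerHeight * 0.92;
const nodes = data.nodes, links = data.links;
const index = new Map(nodes.map((n, i) => [n.id, i]));
nodes.forEach((n, i) => {{
  const a = 2 * Math.PI * i / nodes.length;
  n.x = W / 2 + W / 4 * Math.cos(a);
  n.y = H / 2 + H / 4 * Math.sin(a);
  n.vx = 0; n.vy = 0;
}});
function step() {{
  for (const l of links) {{
    const s = nodes[index.get(l.source)], t = nodes[index.get(l.target)];
    const dx = t.x - s.x, dy = t.y - s.y;
    const dist = Math.hypot(dx, dy) || 1e-6;
    const f = 0.02 * (dist - 40);
    s.vx += f * dx / dist; s.vy += f * dy / dist;
    t.vx -= f * dx / dist; t.vy -= f * dy / dist;
  }}
  for (let i = 0; i < nodes.length; i++)
    for (let j = i + 1; j < nodes.length; j++) {{
      const a = nodes[i], b = nodes[j];
      const dx = b.x - a.x, dy = b.y - a.y;
      const d2 = dx * dx + dy * dy + 1e-6;
      const f = 800 / d2;
      const d = Math.sqrt(d2);
      a.vx -= f * dx / d; a.vy -= f * dy / d;
      b.vx += f * dx / d; b.vy += f * dy / d;
    }}
  for (const n of nodes) {{
    n.vx += 0.002 * (W / 2 - n.x); n.vy += 0.002 * (H / 2 - n.y);
    n.x += n.vx *= 0.85; n.y += n.vy *= 0.85;
  }}
}}
const palette = ['#1f77b4','#ff7f0e','#2ca02c','#d62728','#9467bd',
                 '#8c564b','#e377c2','#7f7f7f','#bcbd22','#17becf'];
function colour(prop) {{
  const vals = nodes.map(n => n.attrs[prop]);
  const numeric = vals.every(v => typeof v === 'number');
  if (numeric) {{
    const lo = Math.min(...vals), hi = Math.max(...vals);
    return v => {{
      const t = hi > lo ? (v - lo) / (hi - lo) : 0.5;
      const c = Math.round(255 * t);
      return `rgb(${{c}},80,${{255 - c}})`;
    }};
  }}
  const cats = [...new Set(vals)].sort();
  return v => palette[cats.indexOf(v) % palette.length];
}}
function render() {{
  const prop = document.getElementById('prop').value;
  const col = colour(prop);
  svg.innerHTML = '';
  for (const l of links) {{
    const s = nodes[index.get(l.source)], t = nodes[index.get(l.target)];
    const e = document.createElementNS('http://www.w3.org/2000/svg', 'line');
    e.setAttribute('x1', s.x); e.setAttribute('y1', s.y);
    e.setAttribute('x2', t.x); e.setAttribute('y2', t.y);
    svg.appendChild(e);
  }}
  for (const n of nodes) {{
    const c = document.createElementNS('http://www.w3.org/2000/svg', 'circle');
    c.setAttribute('cx', n.x); c.setAttribute('cy', n.y);
    c.setAttribute('r', 5);
    c.setAttribute('fill', col(n.attrs[prop]));
    const tip = document.createElementNS('http://www.w3.org/2000/svg', 'title');
    tip.textContent = n.id + ' | ' + prop + ': ' + n.attrs[prop];
    c.appendChild(tip);
    svg.appendChild(c);
  }}
}}
for (let i = 0; i < 300; i++) step();
render();
document.getElementById('prop').addEventListener('change', render);
</script>
</body>
</html>
"""


def export_tree(tree: PocketomeTree, path: str | Path,
                fmt: str | None = None) -> Path:
    """Write the annotated tree as GraphML or a self-contained HTML page.

    *fmt* is ``"graphml"`` or ``"html"``; inferred from the file suffix
    when omitted.  The HTML page embeds the tree data and a small force
    layout with a colour-by-property selector; it references no external
    network resources.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "graphml":
        nx.write_graphml(tree.graph, path)
        return path
    if fmt == "html":
        props = sorted({k for _, d in tree.graph.nodes(data=True) for k in d})
        if not props:
            props = ["degree"]
            for node in tree.graph.nodes:
                tree.graph.nodes[node]["degree"] = tree.graph.degree(node)
        nodes = [{"id": str(n), "attrs": dict(d)}
                 for n, d in tree.graph.nodes(data=True)]
        links = [{"source": str(u), "target": str(v),
                  "distance": d.get("distance", 1.0)}
                 for u, v, d in tree.graph.edges(data=True)]
        options = "".join(f'<option value="{p}">{p}</option>' for p in props)
        path.write_text(_HTML_TEMPLATE.format(
            data=json.dumps({"nodes": nodes, "links": links}), options=options))
        return path
    raise ValueError(f"unknown export format {fmt!r}")


def read_graphml(path: str | Path) -> PocketomeTree:
    """Re-import a GraphML tree exported by :func:`export_tree`."""
    return PocketomeTree(graph=nx.read_graphml(path))
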