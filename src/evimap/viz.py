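"""Static renderers for the six figure families, with sidecar files.

Every renderer writes the figure (SVG by default; PNG/PDF supported) plus
a machine-readable sidecar — ``<basename>.sidecar.json`` — listing every
value that was plotted.  Tests and downstream checks assert on the
sidecar, never on image bytes.  Renderers do no computation: every number
in a sidecar is taken verbatim from the input tables.

Encodings follow the evidence-map conventions: bubble *area* scales
linearly with the encoded count, grid gaps are drawn as outlined empty
cells, chord arcs are proportional to node strengths, and orchard bubbles
above the overflow cap are flagged rather than drawn to scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datamodel import ConfigurationError

KINDS = ("grid_map", "alluvial", "phylo_forest", "coauthor_net", "chord", "orchard")


@dataclass
class PlotSpec:
    kind: str
    out: str | Path
    fmt: str = "svg"
    width: float = 8.0
    height: float = 6.0
    bubble_col: str = "n_studies"
    color_col: str | None = "estimate"
    shape_col: str | None = None
    overflow_cap: float | None = None
    max_bubble_area: float = 1200.0
    encodings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown plot kind {self.kind!r}; one of {KINDS}")


def _sidecar_path(out: str | Path) -> Path:
    out = Path(out)
    return out.with_suffix("").with_suffix(".sidecar.json")


def _write(fig, spec: PlotSpec, sidecar: dict) -> Path:
    out = Path(spec.out).with_suffix("." + spec.fmt)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, format=spec.fmt)
    plt.close(fig)
    _sidecar_path(out).write_text(json.dumps(sidecar, indent=1, sort_keys=True, default=str))
    return out


def render(spec: PlotSpec, data) -> Path:
    """Render ``data`` (the matching module's table(s)) per ``spec``."""
    fn = {
        "grid_map": _render_grid,
        "alluvial": _render_alluvial,
        "phylo_forest": _render_forest,
        "coauthor_net": _render_network,
        "chord": _render_chord,
        "orchard": _render_orchard,
    }[spec.kind]
    return fn(spec, data)


def _require_cols(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c and c not in df.columns]
    if missing:
        raise ConfigurationError(f"{what}: encoding columns {missing} not in data")


def _render_grid(spec: PlotSpec, grid_df: pd.DataFrame) -> Path:
    _require_cols(grid_df, ["row_level", "col_level", spec.bubble_col], "grid_map")
    rows = list(dict.fromkeys(grid_df["row_level"]))
    cols = list(dict.fromkeys(grid_df["col_level"]))
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    marks = []
    vmax = max(float(grid_df[spec.bubble_col].max()), 1.0)
    for _, r in grid_df.iterrows():
        x, y = cols.index(r["col_level"]), rows.index(r["row_level"])
        n = float(r[spec.bubble_col])
        color_val = None
        if spec.color_col and spec.color_col in grid_df.columns and pd.notna(r[spec.color_col]):
            color_val = float(r[spec.color_col])
        mark = {
            "row_level": r["row_level"], "col_level": r["col_level"],
            "bubble_value": n, "color_value": color_val, "empty": n == 0,
        }
        if spec.shape_col and spec.shape_col in grid_df.columns:
            mark["shape_value"] = r[spec.shape_col]
        marks.append(mark)
        if n == 0:
            ax.add_patch(plt.Rectangle((x - 0.4, y - 0.4), 0.8, 0.8,
                                       fill=False, edgecolor="lightgray"))
        else:
            area = spec.max_bubble_area * n / vmax  # area, not radius
            if color_val is not None:
                ax.scatter([x], [y], s=area, c=[color_val],
                           cmap="RdBu_r", vmin=-1, vmax=1, alpha=0.8)
            else:
                ax.scatter([x], [y], s=area, color="tab:blue", alpha=0.8)
            ax.annotate(f"{n:g}", (x, y), ha="center", va="center", fontsize=8)
    ax.set_xticks(range(len(cols)), cols, rotation=45, ha="right")
    ax.set_yticks(range(len(rows)), rows)
    ax.set_xlim(-0.6, len(cols) - 0.4)
    ax.set_ylim(-0.6, len(rows) - 0.4)
    ax.invert_yaxis()
    ax.set_title("Evidence map")
    fig.tight_layout()
    return _write(fig, spec, {"kind": "grid_map", "bubble": spec.bubble_col, "marks": marks})


def _render_alluvial(spec: PlotSpec, flow) -> Path:
    axes, flows = flow.axes, flow.flows
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    positions = {}
    for xi, axis in enumerate(axes):
        y = 0.0
        for lab in flow.strata[axis]:
            total = flow.marginal(axis).get(lab, 0)
            positions[(axis, lab)] = (xi, y, total)
            ax.add_patch(plt.Rectangle((xi - 0.02, y), 0.04, max(total, 0.2), color="gray"))
            ax.annotate(lab, (xi, y + total / 2), fontsize=7, ha="center")
            y += total + 1.0
    marks = []
    for labels, n in flows:
        marks.append({"labels": list(labels), "n_effects": n})
        pts = [positions[(axis, lab)] for axis, lab in zip(axes, labels)]
        xs = [p[0] for p in pts]
        ys = [p[1] + p[2] / 2 for p in pts]
        ax.plot(xs, ys, lw=max(n * 0.8, 0.5), alpha=0.5)
    ax.set_xticks(range(len(axes)), axes)
    ax.set_yticks([])
    ax.set_title("Moderator flows")
    fig.tight_layout()
    return _write(
        fig, spec,
        {"kind": "alluvial", "axes": axes,
         "strata": flow.strata, "flows": marks},
    )


def _render_forest(spec: PlotSpec, data) -> Path:
    """Tree-aligned species forest: tips on the left, estimate whiskers right."""
    ptree, table = data
    tips = ptree.tip_labels
    order = [s for s in tips if s in set(table["species"])]
    extra = [s for s in table["species"] if s not in set(tips)]
    order += extra
    table = table.set_index("species").loc[order].reset_index()
    fig, (axt, axf) = plt.subplots(
        1, 2, figsize=(spec.width, spec.height), sharey=True, width_ratios=[1, 2]
    )
    ypos = {sp: i for i, sp in enumerate(order)}
    for node in ptree.tree.postorder_node_iter():
        if node.is_leaf():
            node._y = ypos.get(node.taxon.label, -1)
        else:
            node._y = float(np.mean([c._y for c in node.child_nodes()]))
        node._x = 1.0 - getattr(node, "grafen_height", 0.0)
    for node in ptree.tree.preorder_node_iter():
        if node.parent_node is not None:
            axt.plot([node.parent_node._x, node._x], [node._y, node._y], c="k", lw=0.8)
            axt.plot([node.parent_node._x] * 2, [node.parent_node._y, node._y], c="k", lw=0.8)
    axt.set_yticks(range(len(order)), order, fontsize=7)
    axt.set_xlabel("Grafen depth")
    marks = []
    for _, r in table.iterrows():
        y = ypos[r["species"]]
        axf.errorbar([r["estimate"]], [y],
                     xerr=[[r["estimate"] - r["ci_low"]], [r["ci_high"] - r["estimate"]]],
                     fmt="o", color="tab:green", capsize=2)
        marks.append({"species": r["species"], "estimate": float(r["estimate"]),
                      "ci_low": float(r["ci_low"]), "ci_high": float(r["ci_high"]),
                      "k_effects": int(r["k_effects"])})
    axf.axvline(0.0, color="gray", lw=0.8, ls="--")
    axf.set_xlabel("Pooled effect (95% CI)")
    fig.tight_layout()
    return _write(fig, spec, {"kind": "phylo_forest", "tip_order": order, "marks": marks})


def _render_network(spec: PlotSpec, data) -> Path:
    import networkx as nx

    net, partition = data
    g = net.to_graph()
    pos = nx.spring_layout(g, seed=int(spec.encodings.get("seed", 0)))
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    colors = [partition.get(n, 0) for n in g.nodes]
    nx.draw_networkx(g, pos=pos, ax=ax, node_color=colors, cmap="tab20",
                     node_size=120, font_size=6,
                     width=[g[u][v]["weight"] for u, v in g.edges])
    ax.set_axis_off()
    edges = [{"from": u, "to": v, "weight": int(g[u][v]["weight"])} for u, v in g.edges]
    nodes = [{"label": n, "cluster": partition.get(n)} for n in g.nodes]
    return _write(fig, spec, {"kind": "coauthor_net", "nodes": nodes, "edges": edges})


def _render_chord(spec: PlotSpec, data) -> Path:
    edges, totals = data
    labels = list(totals)
    total = sum(totals.values()) or 1.0
    # node arcs proportional to strength (perimeter share)
    angles = {}
    start = 0.0
    for lab in labels:
        frac = totals[lab] / total
        angles[lab] = (start, start + 2 * np.pi * frac)
        start += 2 * np.pi * frac
    fig, ax = plt.subplots(figsize=(spec.width, spec.height), subplot_kw={"polar": True})
    for lab, (a0, a1) in angles.items():
        ax.plot(np.linspace(a0, a1, 30), np.ones(30), lw=8)
        ax.annotate(lab, ((a0 + a1) / 2, 1.12), fontsize=7, ha="center")
    for _, e in edges.iterrows():
        a = np.mean(angles[e["from"]])
        b = np.mean(angles[e["to"]])
        ax.plot([a, b], [1, 1], lw=max(float(e["weight"]) * 0.3, 0.3), alpha=0.5)
    ax.set_yticks([])
    ax.set_xticks([])
    sidecar = {
        "kind": "chord",
        "arcs": [{"label": lab, "strength": totals[lab]} for lab in labels],
        "edges": edges.to_dict(orient="records"),
    }
    return _write(fig, spec, sidecar)


def _render_orchard(spec: PlotSpec, orchard) -> Path:
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    groups = orchard.groups
    gy = {g: i for i, g in enumerate(groups)}
    pts = orchard.points
    bmax = max(float(pts["bubble"].max()), 1.0) if len(pts) else 1.0
    marks = []
    rng = np.random.default_rng(int(spec.encodings.get("seed", 0)))
    for _, p in pts.iterrows():
        y = gy[p["group"]] + rng.uniform(-0.25, 0.25)
        shown = min(float(p["bubble"]), spec.overflow_cap) if (
            spec.overflow_cap is not None and p["overflow"]
        ) else float(p["bubble"])
        area = 20 + spec.max_bubble_area * shown / max(
            bmax if spec.overflow_cap is None else min(bmax, spec.overflow_cap), 1.0
        )
        ax.scatter([p["yi"]], [y], s=area, alpha=0.5,
                   edgecolors="red" if p["overflow"] else "none")
        marks.append({"effect_id": p["effect_id"], "group": p["group"],
                      "yi": float(p["yi"]), "bubble": float(p["bubble"]),
                      "overflow": bool(p["overflow"])})
    trunks = []
    for g in groups:
        pe = orchard.pooled[g]
        ax.errorbar([pe.estimate], [gy[g]], xerr=[[pe.estimate - pe.ci_low],
                                                  [pe.ci_high - pe.estimate]],
                    fmt="D", color="k", capsize=4)
        trunks.append({"group": g, "estimate": pe.estimate, "ci_low": pe.ci_low,
                       "ci_high": pe.ci_high, "n_effects": pe.n_effects})
    ax.axvline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_yticks(range(len(groups)), groups)
    ax.set_xlabel("Effect size (Hedges' g)")
    ax.set_title(f"Orchard plot (bubble = {orchard.bubble_metric})")
    fig.tight_layout()
    return _write(fig, spec, {
        "kind": "orchard", "bubble_metric": orchard.bubble_metric,
        "overflow_cap": orchard.overflow_cap, "groups": trunks, "points": marks,
    })
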