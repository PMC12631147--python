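"""Evidence-gap-map grids, alluvial moderator flows, and geographic counts.

An evidence (gap) map cross-tabulates two categorical study
characteristics — typically intervention x outcome — and shows, at each
intersection, how many studies and effects exist and how large the pooled
effect is.  Cells that the schema declares but no study occupies are kept
with zero counts: the gaps are the point of the map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .datamodel import ConfigurationError, Dataset
from .meta import PooledEstimate, fill_effect_sizes, pool_effects

log = logging.getLogger("evimap")


@dataclass
class GridCell:
    row_level: str
    col_level: str
    n_studies: int = 0
    n_effects: int = 0
    pooled: PooledEstimate | None = None
    extra_dim: dict = field(default_factory=dict)


@dataclass
class Grid:
    row_mod: str
    col_mod: str
    row_levels: list[str]
    col_levels: list[str]
    cells: dict[tuple[str, str], GridCell]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.row_levels:
            for c in self.col_levels:
                cell = self.cells[(r, c)]
                row = {
                    "row_level": r,
                    "col_level": c,
                    "n_studies": cell.n_studies,
                    "n_effects": cell.n_effects,
                }
                if cell.pooled is not None:
                    row.update(
                        estimate=cell.pooled.estimate,
                        se=cell.pooled.se,
                        ci_low=cell.pooled.ci_low,
                        ci_high=cell.pooled.ci_high,
                    )
                else:
                    row.update(estimate=None, se=None, ci_low=None, ci_high=None)
                row.update(cell.extra_dim)
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class AlluvialFlow:
    """Effect counts per unique tuple of moderator labels across >= 2 axes."""

    axes: list[str]
    strata: dict[str, list[str]]
    flows: list[tuple[tuple[str, ...], int]]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(zip(self.axes, labels), n_effects=n) for labels, n in self.flows]
        return pd.DataFrame(rows)

    def marginal(self, axis: str) -> dict[str, int]:
        i = self.axes.index(axis)
        out: dict[str, int] = {}
        for labels, n in self.flows:
            out[labels[i]] = out.get(labels[i], 0) + n
        return out


def _check_moderator(dataset: Dataset, name: str) -> None:
    if name not in dataset.moderator_schema:
        raise ConfigurationError(
            f"unknown moderator {name!r}; available: {sorted(dataset.moderator_schema)}"
        )


def _levels(dataset: Dataset, name: str) -> list[str]:
    levels = list(dataset.moderator_schema[name])
    observed = {e.moderator(name) for e in dataset.effects}
    for lab in sorted(observed - set(levels)):
        levels.append(lab)  # "Unknown" or late-declared labels
    return levels


def cross_tabulate(dataset: Dataset, row_mod: str, col_mod: str) -> Grid:
    """Count studies and effects at every (row, col) moderator intersection.

    n_studies counts distinct study IDs per cell (a study spanning cells is
    counted in each); n_effects counts effect rows.  Schema-declared but
    unoccupied cells are present with zero counts.
    """
    _check_moderator(dataset, row_mod)
    _check_moderator(dataset, col_mod)
    row_levels = _levels(dataset, row_mod)
    col_levels = _levels(dataset, col_mod)
    cells = {(r, c): GridCell(r, c) for r in row_levels for c in col_levels}
    studies: dict[tuple[str, str], set[str]] = {k: set() for k in cells}
    for e in dataset.effects:
        key = (e.moderator(row_mod), e.moderator(col_mod))
        cells[key].n_effects += 1
        studies[key].add(e.study_id)
    for key, cell in cells.items():
        cell.n_studies = len(studies[key])
    return Grid(row_mod, col_mod, row_levels, col_levels, cells)


def pool_cells(
    grid: Grid,
    dataset: Dataset,
    method: str = "robust",
    rho: float = 0.5,
    extra_mod: str | None = None,
) -> Grid:
    """Attach a pooled estimate to every non-empty grid cell.

    Default pooling is fixed-effect GLS on a study-clustered VCV with
    cluster-robust variance when a cell holds >= 2 studies; one-effect
    cells pass through the effect and its own standard error.  A cell
    whose pooling fails is reported and left unpooled, not fatal.
    ``extra_mod`` adds a third dimension per cell: the modal label of that
    moderator plus a mixture flag.
    """
    fill_effect_sizes(dataset)
    for (r, c), cell in grid.cells.items():
        subset = [
            e
            for e in dataset.effects
            if e.moderator(grid.row_mod) == r and e.moderator(grid.col_mod) == c
        ]
        if not subset:
            continue
        try:
            cell.pooled = pool_effects(subset, method=method, rho=rho)
        except Exception as exc:  # a failing cell must not kill the map
            log.warning("cell (%s, %s) pooling failed: %s", r, c, exc)
            cell.extra_dim["pooling_error"] = str(exc)
            continue
        if extra_mod is not None:
            labels = [e.moderator(extra_mod) for e in subset]
            modal = max(sorted(set(labels)), key=labels.count)
            cell.extra_dim["modal_" + extra_mod] = modal
            cell.extra_dim["mixed_" + extra_mod] = len(set(labels)) > 1
    return grid


def alluvial_flows(dataset: Dataset, mods: list[str]) -> AlluvialFlow:
    """Effect counts for every observed label tuple across the given moderators."""
    if len(mods) < 2:
        raise ConfigurationError(
            "alluvial flows need >= 2 moderators; use cross_tabulate for one"
        )
    for m in mods:
        _check_moderator(dataset, m)
    counts: dict[tuple[str, ...], int] = {}
    for e in dataset.effects:
        key = tuple(e.moderator(m) for m in mods)
        counts[key] = counts.get(key, 0) + 1
    strata = {m: _levels(dataset, m) for m in mods}
    order = {m: {lab: i for i, lab in enumerate(strata[m])} for m in mods}
    flows = sorted(
        counts.items(),
        key=lambda kv: (-kv[1], tuple(order[m][lab] for m, lab in zip(mods, kv[0]))),
    )
    return AlluvialFlow(axes=list(mods), strata=strata, flows=flows)


def geo_counts(dataset: Dataset, source: str = "bibliography") -> pd.DataFrame:
    """Per-country distinct-study and effect counts.

    ``source="bibliography"`` uses affiliation countries from BibRecords (a
    multi-country study counts once per listed country);
    ``source=<moderator>`` uses a country moderator on the effects.
    """
    rows: dict[str, dict] = {}

    def bump(country: str, study: str, n_eff: int) -> None:
        entry = rows.setdefault(country, {"studies": set(), "n_effects": 0})
        entry["studies"].add(study)
        entry["n_effects"] += n_eff

    if source == "bibliography":
        if not dataset.bibliography:
            raise ConfigurationError("no bibliography attached to the dataset")
        per_study: dict[str, int] = {}
        for e in dataset.effects:
            per_study[e.study_id] = per_study.get(e.study_id, 0) + 1
        missing = 0
        for b in dataset.bibliography:
            n_eff = per_study.get(b.paper_id, 0)
            if not b.countries:
                missing += 1
                continue
            for country in b.countries:
                bump(country, b.paper_id, n_eff)
        if missing:
            log.warning("%d bibliography records without countries excluded", missing)
    else:
        _check_moderator(dataset, source)
        for e in dataset.effects:
            bump(e.moderator(source), e.study_id, 1)
    if not rows:
        log.warning("no country information found; empty geographic table")
    table = pd.DataFrame(
        [
            {"country": c, "n_studies": len(v["studies"]), "n_effects": v["n_effects"]}
            for c, v in sorted(rows.items())
        ],
        columns=["country", "n_studies", "n_effects"],
    )
    return table
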