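"""Alternative impact metrics: retrieval, joining, and plot-ready tables.

Altmetric attention scores plus policy and patent citation counts are
fetched per DOI through a :class:`MetricClient`.  The client is offline
by default: it resolves DOIs against a local fixture table and a JSON
cache, and only touches the network when constructed with
``offline=False`` (the live path targets the public Altmetric details
endpoint and respects a rate limit).  Every response is cached by DOI so
repeated calls are byte-identical and tests never need the network.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .datamodel import AltmetricRecord, ConfigurationError, Dataset
from .evidence_map import Grid, cross_tabulate
from .meta import PooledEstimate, fill_effect_sizes, pool_effects

log = logging.getLogger("evimap")

FIXTURE_COLUMNS = ["doi", "score", "policy_citations", "patent_citations"]


@dataclass
class MetricClient:
    """DOI-keyed metric source with mandatory caching.

    In offline mode (default) every DOI must be covered by the fixture
    table or the cache; unknown DOIs yield a zero record flagged
    ``not_found``.  The live mode uses the public Altmetric details
    endpoint with exponential backoff and at most ``rate_limit`` requests
    per second.
    """

    fixture: str | Path | None = None
    cache_dir: str | Path | None = None
    offline: bool = True
    base_url: str = "https://api.altmetric.com/v1/doi/"
    api_key: str | None = None
    rate_limit: float = 1.0
    max_retries: int = 3
    _fixture_table: dict[str, AltmetricRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.fixture is not None:
            df = pd.read_csv(self.fixture)
            for _, row in df.iterrows():
                rec = AltmetricRecord(
                    doi=str(row["doi"]),
                    score=float(row["score"]),
                    policy_citations=int(row["policy_citations"]),
                    patent_citations=int(row["patent_citations"]),
                    retrieved_at="fixture",
                )
                self._fixture_table[rec.doi] = rec

    def _cache_path(self, doi: str) -> Path | None:
        if self.cache_dir is None:
            return None
        safe = doi.replace("/", "_").replace(":", "_")
        return Path(self.cache_dir) / f"{safe}.json"

    def _from_cache(self, doi: str) -> AltmetricRecord | None:
        p = self._cache_path(doi)
        if p is not None and p.exists():
            return AltmetricRecord(**json.loads(p.read_text()))
        return None

    def _to_cache(self, rec: AltmetricRecord) -> None:
        p = self._cache_path(rec.doi)
        if p is not None:
            p.parent.mkdir(parents=True, exist_ok=True)
            p.write_text(json.dumps(rec.__dict__, sort_keys=True))

    def get(self, doi: str) -> AltmetricRecord:
        doi = doi.strip().lower()
        cached = self._from_cache(doi)
        if cached is not None:
            return cached
        if doi in self._fixture_table:
            rec = self._fixture_table[doi]
        elif self.offline:
            rec = AltmetricRecord(doi=doi, retrieved_at="offline", not_found=True)
        else:
            rec = self._fetch_live(doi)
        self._to_cache(rec)
        return rec

    def _fetch_live(self, doi: str) -> AltmetricRecord:
        import urllib.error
        import urllib.request

        url = self.base_url + doi
        if self.api_key:
            url += f"?key={self.api_key}"
        delay = 1.0 / max(self.rate_limit, 1e-6)
        for attempt in range(self.max_retries):
            time.sleep(delay if attempt == 0 else delay * 2**attempt)
            try:
                with urllib.request.urlopen(url, timeout=30) as resp:
                    payload = json.loads(resp.read().decode("utf-8"))
                return AltmetricRecord(
                    doi=doi,
                    score=float(payload.get("score", 0.0)),
                    policy_citations=int(payload.get("cited_by_policies_count", 0)),
                    patent_citations=int(payload.get("cited_by_patents_count", 0)),
                    retrieved_at=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
                )
            except urllib.error.HTTPError as exc:
                if exc.code == 404:
                    return AltmetricRecord(
                        doi=doi, retrieved_at="live", not_found=True
                    )
                log.warning("HTTP %s for %s (attempt %d)", exc.code, doi, attempt + 1)
            except Exception as exc:  # noqa: BLE001 — batch must continue
                log.warning("fetch failed for %s: %s", doi, exc)
        return AltmetricRecord(doi=doi, retrieved_at="error", not_found=True)


def fetch_metrics(dois: list[str], client: MetricClient) -> list[AltmetricRecord]:
    """One record per DOI (order preserved); unknown DOIs are flagged zeros."""
    records = [client.get(d) for d in dois]
    missing = [r.doi for r in records if r.not_found]
    if missing and client.offline and client.fixture is not None:
        log.warning("offline fixture does not cover %d DOIs: %s", len(missing), missing)
    return records


def join_metrics(dataset: Dataset, records: list[AltmetricRecord]) -> pd.DataFrame:
    """Study-level left join of altmetric records on lower-cased DOI.

    Every study produces exactly one output row regardless of match rate;
    unmatched studies carry NaN metrics and are counted in the log.
    """
    by_doi = {r.doi: r for r in records}
    rows = []
    unmatched = 0
    for sid in dataset.study_ids:
        bib = dataset.bib_for(sid)
        doi = bib.doi if bib is not None and bib.doi else None
        rec = by_doi.get(doi) if doi else None
        if rec is None or rec.not_found:
            unmatched += 1
            rows.append(
                {"study_id": sid, "doi": doi, "score": float("nan"),
                 "policy_citations": float("nan"), "patent_citations": float("nan"),
                 "matched": False}
            )
        else:
            rows.append(
                {"study_id": sid, "doi": doi, "score": rec.score,
                 "policy_citations": rec.policy_citations,
                 "patent_citations": rec.patent_citations, "matched": True}
            )
    if unmatched:
        log.warning("%d studies without matched altmetrics", unmatched)
    return pd.DataFrame(rows)


@dataclass
class OrchardData:
    """Per-group pooled estimates plus per-effect bubble points."""

    groups: list[str]
    pooled: dict[str, PooledEstimate]
    points: pd.DataFrame  # effect_id, group, yi, bubble, overflow
    bubble_metric: str
    overflow_cap: float | None


def _metric_column(metric: str) -> list[str]:
    cols = {
        "score": ["score"],
        "policy": ["policy_citations"],
        "patent": ["patent_citations"],
        "policy+patent": ["policy_citations", "patent_citations"],
    }
    if metric not in cols:
        raise ConfigurationError(f"unknown bubble metric {metric!r}")
    return cols[metric]


def orchard_data(
    dataset: Dataset,
    joined: pd.DataFrame,
    group_mod: str,
    bubble_metric: str = "score",
    method: str = "robust",
    rho: float = 0.5,
    overflow_cap: float | None = None,
) -> OrchardData:
    """Orchard-plot table: group pooled effects, bubbles sized by a metric.

    Bubble size is the chosen metric of the effect's study; sizes above
    ``overflow_cap`` are flagged rather than drawn to scale.  Empty groups
    are omitted with a warning.
    """
    if group_mod not in dataset.moderator_schema:
        raise ConfigurationError(
            f"unknown moderator {group_mod!r}; available: {sorted(dataset.moderator_schema)}"
        )
    fill_effect_sizes(dataset)
    cols = _metric_column(bubble_metric)
    metric_of = {
        row["study_id"]: sum(0.0 if pd.isna(row[c]) else float(row[c]) for c in cols)
        for _, row in joined.iterrows()
    }
    groups: list[str] = []
    for lab in dataset.moderator_schema[group_mod]:
        if any(e.moderator(group_mod) == lab for e in dataset.effects):
            groups.append(lab)
        else:
            log.warning("group %r has no effects; omitted from orchard data", lab)
    pooled = {}
    points = []
    for lab in groups:
        effs = [e for e in dataset.effects if e.moderator(group_mod) == lab]
        pooled[lab] = pool_effects(effs, method=method, rho=rho)
        for e in effs:
            bubble = metric_of.get(e.study_id, 0.0)
            points.append(
                {
                    "effect_id": e.effect_id,
                    "group": lab,
                    "yi": e.yi,
                    "bubble": bubble,
                    "overflow": bool(overflow_cap is not None and bubble > overflow_cap),
                }
            )
    return OrchardData(
        groups=groups,
        pooled=pooled,
        points=pd.DataFrame(points),
        bubble_metric=bubble_metric,
        overflow_cap=overflow_cap,
    )


def impact_grid(
    dataset: Dataset,
    joined: pd.DataFrame,
    row_mod: str,
    col_mod: str,
) -> pd.DataFrame:
    """Impact metrics per evidence-map cell.

    Per cell: total policy citations, total patent citations and mean
    Altmetric score over the cell's distinct studies.  Empty cells appear
    with zero totals so gaps remain visible.
    """
    grid: Grid = cross_tabulate(dataset, row_mod, col_mod)
    by_study = joined.set_index("study_id")
    rows = []
    for r in grid.row_levels:
        for c in grid.col_levels:
            studies = sorted(
                {
                    e.study_id
                    for e in dataset.effects
                    if e.moderator(row_mod) == r and e.moderator(col_mod) == c
                }
            )
            sub = by_study.loc[[s for s in studies if s in by_study.index]]
            policy = float(sub["policy_citations"].fillna(0).sum()) if len(sub) else 0.0
            patent = float(sub["patent_citations"].fillna(0).sum()) if len(sub) else 0.0
            score = float(sub["score"].mean()) if len(sub) and sub["score"].notna().any() else float("nan")
            rows.append(
                {
                    "row_level": r,
                    "col_level": c,
                    "n_studies": len(studies),
                    "policy_citations": policy,
                    "patent_citations": patent,
                    "mean_score": score,
                }
            )
    return pd.DataFrame(rows)
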