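"""Readers and writers for the toolkit's file formats.

Effect tables, country tables and altmetric fixtures travel as delimited
text (comma by default, RFC-4180 quoting, UTF-8; tab configurable).
Bibliography can arrive as BibTeX or as delimited text with ";"-separated
author / country / reference fields.  All writers emit CSV.

The BibTeX reader is intentionally minimal: it handles ``@type{key, field
= {...} | "..." | bare,}`` entries with balanced braces, which covers
exported reference lists; it is not a general-purpose TeX parser.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

from .datamodel import (
    BibRecord,
    ConfigurationError,
    Dataset,
    EffectRecord,
    RawOutcome,
    ValidationError,
    normalize_author,
)

log = logging.getLogger("evimap")

DEFAULT_COLUMN_MAP = {
    "study_id": "study_id",
    "effect_id": "effect_id",
    "yi": "yi",
    "vi": "vi",
    "species": "species",
    "author_cluster": "author_cluster",
    "m1": "m1",
    "m2": "m2",
    "s1": "s1",
    "s2": "s2",
    "n1": "n1",
    "n2": "n2",
}
_RAW_COLS = ("m1", "m2", "s1", "s2", "n1", "n2")
_SPECIAL = set(DEFAULT_COLUMN_MAP) | {"moderators"}


def read_effects(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    moderators: list[str] | None = None,
    sep: str = ",",
    moderator_schema: dict[str, list[str]] | None = None,
) -> Dataset:
    """Read an effect-size table into a :class:`Dataset`.

    ``column_map`` maps canonical names (study_id, effect_id, yi, vi,
    m1..n2, species, author_cluster) to the file's column headers;
    unmapped canonical names fall back to identical headers.  Columns not
    claimed by the map are treated as categorical moderators unless
    ``moderators`` names them explicitly.  When yi/vi are absent but raw
    two-group summaries are present, yi/vi are left unset for the meta
    engine to fill.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for mandatory in ("study_id", "effect_id"):
        if cmap[mandatory] not in df.columns:
            raise ConfigurationError(
                f"missing mandatory column {cmap[mandatory]!r} for {mandatory}"
            )
    have_yi = cmap["yi"] in df.columns and cmap["vi"] in df.columns
    have_raw = all(cmap[c] in df.columns for c in _RAW_COLS)
    if not have_yi and not have_raw:
        raise ConfigurationError(
            f"need either yi/vi columns ({cmap['yi']!r}, {cmap['vi']!r}) "
            f"or raw-outcome columns {[cmap[c] for c in _RAW_COLS]}"
        )
    claimed = {cmap[k] for k in cmap}
    if moderators is None:
        moderators = [c for c in df.columns if c not in claimed]
    effects = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # header is line 1
        yi = vi = None
        if have_yi and row[cmap["yi"]] != "":
            yi = _num(row[cmap["yi"]], cmap["yi"], rownum)
            vi = _num(row[cmap["vi"]], cmap["vi"], rownum)
            if vi <= 0:
                raise ValidationError(
                    f"row {rownum}: sampling variance {cmap['vi']} = {vi} must be > 0"
                )
        raw = None
        if have_raw and row[cmap["m1"]] != "":
            raw = RawOutcome(
                m1=_num(row[cmap["m1"]], "m1", rownum),
                m2=_num(row[cmap["m2"]], "m2", rownum),
                s1=_num(row[cmap["s1"]], "s1", rownum),
                s2=_num(row[cmap["s2"]], "s2", rownum),
                n1=int(_num(row[cmap["n1"]], "n1", rownum)),
                n2=int(_num(row[cmap["n2"]], "n2", rownum)),
            )
        effects.append(
            EffectRecord(
                study_id=row[cmap["study_id"]],
                effect_id=row[cmap["effect_id"]],
                yi=yi,
                vi=vi,
                species=_opt(row, cmap["species"]),
                author_cluster=_opt(row, cmap["author_cluster"]),
                moderators={m: row[m] for m in moderators if row.get(m, "") != ""},
                raw=raw,
            )
        )
    ds = Dataset(effects=effects)
    if moderator_schema:
        ds.moderator_schema = moderator_schema
    return ds


def write_effects(dataset: Dataset, path: str | Path, sep: str = ",") -> None:
    """Write an effect table; inverse of :func:`read_effects` for yi/vi tables."""
    mods = list(dataset.moderator_schema)
    rows = []
    for e in dataset.effects:
        row = {
            "study_id": e.study_id,
            "effect_id": e.effect_id,
            "yi": e.yi,
            "vi": e.vi,
            "species": e.species or "",
            "author_cluster": e.author_cluster or "",
        }
        if e.raw is not None:
            row.update(
                m1=e.raw.m1, m2=e.raw.m2, s1=e.raw.s1, s2=e.raw.s2,
                n1=e.raw.n1, n2=e.raw.n2,
            )
        for m in mods:
            row[m] = e.moderators.get(m, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, encoding="utf-8")


def write_table(result, path: str | Path, sep: str = ",") -> None:
    """Write any tabular result (DataFrame or list of dicts) as delimited text."""
    if not isinstance(result, pd.DataFrame):
        result = pd.DataFrame(result)
    result.to_csv(path, sep=sep, index=False, encoding="utf-8")


# -- bibliography ----------------------------------------------------------

_ENTRY_RE = re.compile(r"@(\w+)\s*\{", re.IGNORECASE)


def read_bibliography(
    path: str | Path, format: str = "bibtex", sep: str = ","
) -> list[BibRecord]:
    """Read bibliographic records from BibTeX or delimited text.

    Author names are normalized to "surname initials"; DOIs lower-cased;
    records sharing a non-empty DOI are deduplicated (first kept, logged).
    """
    if format == "bibtex":
        records = _read_bibtex(Path(path).read_text(encoding="utf-8"))
    elif format == "delimited":
        records = _read_bib_delimited(path, sep=sep)
    else:
        raise ConfigurationError(f"unknown bibliography format {format!r}")
    seen_ids: set[str] = set()
    by_doi: dict[str, BibRecord] = {}
    out: list[BibRecord] = []
    dropped = 0
    for rec in records:
        if rec.paper_id in seen_ids:
            raise ValidationError(f"duplicate paper_id {rec.paper_id!r}")
        seen_ids.add(rec.paper_id)
        if rec.doi and rec.doi in by_doi:
            dropped += 1
            continue
        if rec.doi:
            by_doi[rec.doi] = rec
        out.append(rec)
    if dropped:
        log.warning("deduplicated %d bibliography records sharing a DOI", dropped)
    return out


def _read_bibtex(text: str) -> list[BibRecord]:
    records = []
    skipped = 0
    for m in _ENTRY_RE.finditer(text):
        if m.group(1).lower() in ("comment", "preamble", "string"):
            continue
        body, _ = _balanced(text, m.end() - 1)
        try:
            records.append(_bib_entry(body))
        except (ValidationError, ValueError) as exc:
            skipped += 1
            log.warning("skipping unparseable BibTeX entry: %s", exc)
    if skipped:
        log.warning("skipped %d unparseable BibTeX entries", skipped)
    return records


def _balanced(text: str, start: int) -> tuple[str, int]:
    """Content of the brace group opening at ``start``; returns (content, end)."""
    assert text[start] == "{"
    depth = 0
    for i in range(start, len(text)):
        if text[i] == "{":
            depth += 1
        elif text[i] == "}":
            depth -= 1
            if depth == 0:
                return text[start + 1 : i], i
    raise ValueError("unbalanced braces in BibTeX entry")

def _bib_entry(body: str) -> BibRecord:
    key, _, rest = body.partition(",")
    fields: dict[str, str] = {}
    i = 0
    while i < len(rest):
        eq = rest.find("=", i)
        if eq < 0:
            break
        name = rest[i:eq].strip().strip(",").strip().lower()
        j = eq + 1
        while j < len(rest) and rest[j] in " \t\r\n":
            j += 1
        if j >= len(rest):
            break
        if rest[j] == "{":
            value, end = _balanced(rest, j)
            i = end + 1
        elif rest[j] == '"':
            end = rest.find('"', j + 1)
            value = rest[j + 1 : end]
            i = end + 1
        else:
            end = rest.find(",", j)
            end = end if end >= 0 else len(rest)
            value = rest[j:end].strip()
            i = end
        fields[name] = re.sub(r"\s+", " ", value.replace("{", "").replace("}", "")).strip()
    authors = [normalize_author(a) for a in re.split(r"\s+and\s+", fields.get("author", "")) if a.strip()]
    return BibRecord(
        paper_id=key.strip(),
        authors=authors,
        year=int(fields["year"]) if fields.get("year", "").isdigit() else None,
        journal=fields.get("journal", ""),
        doi=fields.get("doi") or None,
        countries=_split_list(fields.get("country", fields.get("countries", ""))),
        funder=fields.get("funder") or None,
        references=_split_list(fields.get("references", fields.get("cited-references", ""))),
    )


def _read_bib_delimited(path: str | Path, sep: str = ",") -> list[BibRecord]:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "paper_id" not in df.columns or "authors" not in df.columns:
        raise ConfigurationError("delimited bibliography needs paper_id and authors columns")
    records = []
    for _, row in df.iterrows():
        records.append(
            BibRecord(
                paper_id=row["paper_id"],
                authors=[normalize_author(a) for a in _split_list(row["authors"]) if a],
                year=int(row["year"]) if row.get("year", "").strip().isdigit() else None,
                journal=row.get("journal", ""),
                doi=row.get("doi", "") or None,
                countries=_split_list(row.get("countries", "")),
                funder=row.get("funder", "") or None,
                references=_split_list(row.get("references", "")),
            )
        )
    return records


def write_bibliography(records: list[BibRecord], path: str | Path) -> None:
    rows = [
        {
            "paper_id": r.paper_id,
            "authors": ";".join(r.authors),
            "year": r.year,
            "journal": r.journal,
            "doi": r.doi or "",
            "countries": ";".join(r.countries),
            "funder": r.funder or "",
            "references": ";".join(r.references),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def write_bibtex(records: list[BibRecord], path: str | Path) -> None:
    """Write records as BibTeX (round-trips through :func:`read_bibliography`)."""
    chunks = []
    for r in records:
        fields = [f"  author = {{{' and '.join(r.authors)}}}"]
        if r.year is not None:
            fields.append(f"  year = {{{r.year}}}")
        if r.journal:
            fields.append(f"  journal = {{{r.journal}}}")
        if r.doi:
            fields.append(f"  doi = {{{r.doi}}}")
        if r.countries:
            fields.append(f"  country = {{{';'.join(r.countries)}}}")
        if r.funder:
            fields.append(f"  funder = {{{r.funder}}}")
        if r.references:
            fields.append(f"  references = {{{';'.join(r.references)}}}")
        chunks.append(f"@article{{{r.paper_id},\n" + ",\n".join(fields) + "\n}\n")
    Path(path).write_text("\n".join(chunks), encoding="utf-8")


def _split_list(value: str) -> list[str]:
    return [v.strip() for v in value.split(";") if v.strip()]


def _opt(row, col: str) -> str | None:
    v = row.get(col, "")
    return v if v != "" else None


def _num(value: str, col: str, rownum: int) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ValidationError(f"row {rownum}: non-numeric value {value!r} in column {col!r}") from exc
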