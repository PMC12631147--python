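"""Core data model for meta-analytic evidence bases.

The toolkit revolves around three record kinds: effect sizes with their
sampling variances (:class:`EffectRecord`), bibliographic metadata for the
primary studies (:class:`BibRecord`), and alternative impact metrics keyed
by DOI (:class:`AltmetricRecord`).  A :class:`Dataset` bundles effects,
bibliography and the moderator schema (the ordered category levels of each
categorical study characteristic).
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

UNKNOWN_LEVEL = "Unknown"


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


class ConfigurationError(ValueError):
    """A caller named a column, moderator or option that does not exist."""


@dataclass(frozen=True)
class RawOutcome:
    """Two-group summary statistics (means, SDs, group sizes).

    These are the inputs to the Hedges' g standardized mean difference;
    ``s1, s2 > 0`` and ``n1 + n2 >= 4`` so the small-sample correction is
    defined.
    """

    m1: float
    m2: float
    s1: float
    s2: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValidationError("group SDs must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise ValidationError("group sizes must be >= 2")
        if self.n1 + self.n2 < 4:
            raise ValidationError("n1 + n2 must be >= 4")


@dataclass
class EffectRecord:
    """One effect size with its sampling variance and clustering labels.

    ``yi`` is on a standardized (unitless) scale; ``vi`` is its sampling
    variance.  Either ``yi``/``vi`` or ``raw`` must be present; when only
    raw two-group summaries are given, ``yi`` and ``vi`` stay ``None``
    until the meta engine computes Hedges' g.
    """

    study_id: str
    effect_id: str
    yi: float | None = None
    vi: float | None = None
    species: str | None = None
    author_cluster: str | None = None
    moderators: dict[str, str] = field(default_factory=dict)
    raw: RawOutcome | None = None

    def __post_init__(self) -> None:
        if self.vi is not None and self.vi <= 0:
            raise ValidationError(
                f"effect {self.effect_id!r}: sampling variance vi must be > 0, got {self.vi}"
            )
        if self.yi is not None and not _finite(self.yi):
            raise ValidationError(f"effect {self.effect_id!r}: yi must be finite")

    def moderator(self, name: str) -> str:
        """Return the label of moderator ``name``, mapping missing to 'Unknown'."""
        value = self.moderators.get(name)
        if value is None or value == "":
            return UNKNOWN_LEVEL
        return value


@dataclass
class BibRecord:
    """Bibliographic metadata for one paper.

    Author names are stored normalized ("surname initials", lower-case,
    accents stripped); DOIs are lower-cased; ``references`` are the keys of
    the paper's cited references (exact-string matching downstream).
    """

    paper_id: str
    authors: list[str]
    year: int | None = None
    journal: str = ""
    doi: str | None = None
    countries: list[str] = field(default_factory=list)
    funder: str | None = None
    references: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.authors:
            raise ValidationError(f"paper {self.paper_id!r}: authors must be non-empty")
        if self.doi is not None:
            self.doi = self.doi.strip().lower() or None


@dataclass
class AltmetricRecord:
    """Alternative impact metrics for one DOI."""

    doi: str
    score: float = 0.0
    policy_citations: int = 0
    patent_citations: int = 0
    retrieved_at: str = ""
    not_found: bool = False

    def __post_init__(self) -> None:
        self.doi = self.doi.strip().lower()
        if self.score < 0:
            raise ValidationError(f"{self.doi}: Altmetric score must be >= 0")
        if self.policy_citations < 0 or self.patent_citations < 0:
            raise ValidationError(f"{self.doi}: citation counts must be >= 0")


@dataclass
class Dataset:
    """Effects plus optional bibliography and the moderator schema.

    ``moderator_schema`` maps each moderator name to its ordered category
    levels (first-appearance order unless user-declared); missing values
    are carried as the explicit level ``"Unknown"`` so that gap and flow
    displays can show missingness.
    """

    effects: list[EffectRecord]
    bibliography: list[BibRecord] = field(default_factory=list)
    moderator_schema: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.effects:
            if e.effect_id in seen:
                raise ValidationError(f"duplicate effect_id {e.effect_id!r}")
            seen.add(e.effect_id)
        if not self.moderator_schema:
            self.moderator_schema = infer_schema(self.effects)

    @property
    def study_ids(self) -> list[str]:
        out: list[str] = []
        for e in self.effects:
            if e.study_id not in out:
                out.append(e.study_id)
        return out

    def bib_for(self, study_id: str) -> BibRecord | None:
        hits = [b for b in self.bibliography if b.paper_id == study_id]
        if len(hits) > 1:
            raise ValidationError(f"study {study_id!r} resolves to {len(hits)} BibRecords")
        return hits[0] if hits else None

    def subset(self, keep) -> "Dataset":
        """New Dataset restricted to effects where ``keep(effect)`` is true."""
        effects = [e for e in self.effects if keep(e)]
        return Dataset(
            effects=effects,
            bibliography=self.bibliography,
            moderator_schema=dict(self.moderator_schema),
        )


def infer_schema(effects: list[EffectRecord]) -> dict[str, list[str]]:
    """Moderator schema in first-appearance order, 'Unknown' appended last when observed."""
    schema: dict[str, list[str]] = {}
    names: list[str] = []
    for e in effects:
        for name in e.moderators:
            if name not in names:
                names.append(name)
    unknown_seen = {name: False for name in names}
    for name in names:
        levels: list[str] = []
        for e in effects:
            lab = e.moderator(name)
            if lab == UNKNOWN_LEVEL:
                unknown_seen[name] = True
                continue
            if lab not in levels:
                levels.append(lab)
        if unknown_seen[name]:
            levels.append(UNKNOWN_LEVEL)
        schema[name] = levels
    return schema


def normalize_author(name: str) -> str:
    """Collapse an author string to 'surname initials', lower-case, accents stripped.

    Accepts "Surname, Given Names" or "Given Surname"; idempotent, so
    already-normalized strings pass through unchanged.
    """
    s = unicodedata.normalize("NFKD", name)
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = s.strip().lower().replace(".", " ")
    if not s:
        return ""
    if "," in s:
        surname, _, given = s.partition(",")
        surname = surname.strip()
        initials = "".join(w[0] for w in given.split())
    else:
        parts = s.split()
        if len(parts) == 1:
            return parts[0]
        # "surname initials" (our own output) is two tokens with a short tail;
        # anything else is read as "given names surname".
        if len(parts) == 2 and len(parts[1]) <= 4:
            surname, initials = parts[0], parts[1]
        else:
            surname = parts[-1]
            initials = "".join(w[0] for w in parts[:-1])
    surname = "-".join(filter(None, surname.split()))
    return f"{surname} {initials}".strip()


def _finite(x: float) -> bool:
    return x == x and x not in (float("inf"), float("-inf"))
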