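"""Query-level classifiers.

Three small rule systems applied to raw query text:

* :func:`is_msd_query` — detection of queries about mood-stabilizing
  drugs (MSD): specific drug names, "mood stabiliz\\*" phrases, and the
  ambiguous term "lithium", which counts only when no battery/metal
  context term co-occurs in the query.
* :func:`classify_query` — multi-label topical classification against a
  transparent 63-category keyword taxonomy (a stand-in for commercial
  query classifiers; user-replaceable via YAML).
* :func:`self_reference` — whether a query mentioning a mood disorder is
  phrased in the first person ("I have severe depression") or about
  another person ("my wife bipolar treatment").

Tokenization is shared: lowercase, split on non-alphanumerics (keeping
apostrophes so "i'm" survives); multiword patterns match as contiguous
token subsequences, so matching is independent of surrounding words.

:func:`annotate` applies the classifiers to a whole log, deduplicating
on unique query texts, and appends ``msd_flag``, ``matched``,
``drug_names`` and ``categories`` columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .logio import SearchLog

_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def _contains_phrase(tokens: list[str], phrase_tokens: tuple[str, ...]) -> bool:
    n = len(phrase_tokens)
    if n == 1:
        return phrase_tokens[0] in tokens
    return any(tuple(tokens[i : i + n]) == phrase_tokens for i in range(len(tokens) - n + 1))


def _load_default_yaml() -> dict:
    with resources.files("episodelog.data").joinpath("default_lexicon.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class DrugLexicon:
    msd_names: tuple[str, ...]
    stabilizer_stems: tuple[str, ...]
    lithium_term: str
    lithium_exclusions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.lithium_exclusions:
            raise ValueError("lithium_exclusions must be non-empty")
        for entry in (*self.msd_names, *self.stabilizer_stems, self.lithium_term):
            if entry != entry.lower():
                raise ValueError(f"lexicon entries must be lowercase: {entry!r}")

    @cached_property
    def _name_tokens(self) -> tuple[tuple[str, tuple[str, ...]], ...]:
        return tuple((name, tuple(tokenize(name))) for name in self.msd_names)


@dataclass(frozen=True)
class CategoryLexicon:
    """Ordered mapping of exactly 63 category names to keyword patterns."""

    categories: dict[str, tuple[str, ...]]
    multi_label: bool = True

    def __post_init__(self) -> None:
        if len(self.categories) != 63:
            raise ValueError(f"expected exactly 63 categories, got {len(self.categories)}")
        if len(set(self.categories)) != 63:
            raise ValueError("category names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.categories)

    @cached_property
    def name_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.categories)}

    @cached_property
    def _single_token_index(self) -> dict[str, frozenset[str]]:
        """token -> categories matched by that single-token keyword."""
        index: dict[str, set[str]] = {}
        for cat, keywords in self.categories.items():
            for kw in keywords:
                toks = tokenize(kw)
                if len(toks) == 1:
                    index.setdefault(toks[0], set()).add(cat)
        return {tok: frozenset(cats) for tok, cats in index.items()}

    @cached_property
    def _multi_token_patterns(self) -> tuple[tuple[str, tuple[str, ...]], ...]:
        out = []
        for cat, keywords in self.categories.items():
            for kw in keywords:
                toks = tuple(tokenize(kw))
                if len(toks) > 1:
                    out.append((cat, toks))
        return tuple(out)

    @cached_property
    def all_keyword_tokens(self) -> frozenset[str]:
        toks: set[str] = set()
        for keywords in self.categories.values():
            for kw in keywords:
                toks.update(tokenize(kw))
        return frozenset(toks)


@dataclass(frozen=True)
class MoodTermSet:
    disorder_terms: tuple[str, ...]
    first_person_markers: tuple[str, ...]
    other_person_markers: tuple[str, ...]
    comorbid_terms: tuple[str, ...]


def default_drug_lexicon() -> DrugLexicon:
    raw = _load_default_yaml()["drug_lexicon"]
    return DrugLexicon(
        msd_names=tuple(raw["msd_names"]),
        stabilizer_stems=tuple(raw["stabilizer_stems"]),
        lithium_term=raw["lithium_term"],
        lithium_exclusions=frozenset(raw["lithium_exclusions"]),
    )


def default_category_lexicon() -> CategoryLexicon:
    raw = _load_default_yaml()["categories"]
    return CategoryLexicon(categories={name: tuple(kws) for name, kws in raw.items()})


def default_mood_terms() -> MoodTermSet:
    raw = _load_default_yaml()["mood_terms"]
    return MoodTermSet(
        disorder_terms=tuple(raw["disorder_terms"]),
        first_person_markers=tuple(raw["first_person_markers"]),
        other_person_markers=tuple(raw["other_person_markers"]),
        comorbid_terms=tuple(raw["comorbid_terms"]),
    )


def load_lexicon_file(path: str | Path) -> tuple[DrugLexicon, CategoryLexicon, MoodTermSet]:
    """Load a user-supplied YAML lexicon with the same layout as the default."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    drug = raw.get("drug_lexicon")
    cats = raw.get("categories")
    mood = raw.get("mood_terms")
    dl = (
        DrugLexicon(
            msd_names=tuple(drug["msd_names"]),
            stabilizer_stems=tuple(drug["stabilizer_stems"]),
            lithium_term=drug["lithium_term"],
            lithium_exclusions=frozenset(drug["lithium_exclusions"]),
        )
        if drug
        else default_drug_lexicon()
    )
    cl = (
        CategoryLexicon(categories={name: tuple(kws) for name, kws in cats.items()})
        if cats
        else default_category_lexicon()
    )
    mt = (
        MoodTermSet(
            disorder_terms=tuple(mood["disorder_terms"]),
            first_person_markers=tuple(mood["first_person_markers"]),
            other_person_markers=tuple(mood["other_person_markers"]),
            comorbid_terms=tuple(mood["comorbid_terms"]),
        )
        if mood
        else default_mood_terms()
    )
    return dl, cl, mt


def drug_names_in(text: str, lex: DrugLexicon) -> tuple[str, ...]:
    """All specific MSD drug names mentioned in the query, in lexicon order."""
    tokens = tokenize(text)
    return tuple(name for name, toks in lex._name_tokens if _contains_phrase(tokens, toks))


def is_msd_query(text: str, lex: DrugLexicon) -> tuple[bool, str | None]:
    """Detect an MSD query and say what matched.

    Returns ``(flag, matched)`` with ``matched`` one of a specific drug
    name, ``"stabilizer-phrase"``, ``"lithium"``, or ``None``. Lithium
    matches only when no exclusion term co-occurs in the same query.
    """
    tokens = tokenize(text)
    for name, toks in lex._name_tokens:
        if _contains_phrase(tokens, toks):
            return True, name
    lowered = text.lower()
    if any(stem in lowered for stem in lex.stabilizer_stems):
        return True, "stabilizer-phrase"
    if lex.lithium_term in tokens and not any(t in lex.lithium_exclusions for t in tokens):
        return True, "lithium"
    return False, None


def classify_query(text: str, lex: CategoryLexicon) -> set[str]:
    tokens = tokenize(text)
    cats: set[str] = set()
    index = lex._single_token_index
    for tok in tokens:
        hit = index.get(tok)
        if hit:
            cats |= hit
    for cat, pattern in lex._multi_token_patterns:
        if cat not in cats and _contains_phrase(tokens, pattern):
            cats.add(cat)
    return cats


def self_reference(text: str, terms: MoodTermSet) -> str:
    """Classify a query as 'first_person', 'other_person' or 'none'.

    Returns 'none' when no mood-disorder term is present regardless of
    pronouns. Other-person patterns ("my wife" ...) take precedence over
    the bare first-person markers ("i", "my"), and matching does not
    depend on token positions.
    """
    tokens = tokenize(text)
    if not any(_contains_phrase(tokens, tuple(tokenize(t))) for t in terms.disorder_terms):
        return "none"
    if any(_contains_phrase(tokens, tuple(tokenize(m))) for m in terms.other_person_markers):
        return "other_person"
    if any(_contains_phrase(tokens, tuple(tokenize(m))) for m in terms.first_person_markers):
        return "first_person"
    return "none"


@dataclass(frozen=True)
class SelfOtherResult:
    n_first: int
    n_other: int
    ratio: float  # nan (flagged) when n_other == 0
    chi_square_p: float

    @property
    def undefined(self) -> bool:
        return self.n_other == 0


def self_other_from_counts(n_first: int, n_other: int) -> SelfOtherResult:
    """Ratio of first-person to other-person mood queries plus a
    goodness-of-fit chi-square against equal expected counts."""
    total = n_first + n_other
    if total == 0:
        return SelfOtherResult(0, 0, float("nan"), float("nan"))
    chi2 = stats.chisquare([n_first, n_other])
    ratio = n_first / n_other if n_other else float("nan")
    return SelfOtherResult(n_first, n_other, ratio, float(chi2.pvalue))


def self_other_ratio(log: SearchLog, terms: MoodTermSet | None = None) -> SelfOtherResult:
    """Count unique query texts mentioning a mood disorder in the first
    person vs about another person; duplicates of a text count once."""
    terms = terms or default_mood_terms()
    uniq = pd.unique(log.df["query_text"].str.lower())
    n_first = n_other = 0
    for text in uniq:
        ref = self_reference(text, terms)
        if ref == "first_person":
            n_first += 1
        elif ref == "other_person":
            n_other += 1
    return self_other_from_counts(n_first, n_other)


@dataclass(frozen=True)
class ComorbidResult:
    n_mood_users: int
    n_comorbid_users: int
    ratio: float

    @property
    def undefined(self) -> bool:
        return self.n_comorbid_users == 0


def comorbid_ratio(
    log: SearchLog,
    lex: DrugLexicon | None = None,
    terms: MoodTermSet | None = None,
) -> ComorbidResult:
    """User-level ratio of MSD-querying users who mention mood-disorder
    terms to those who mention migraine/seizure terms (each user counted
    once per side); an empty denominator is flagged, not raised."""
    lex = lex or default_drug_lexicon()
    terms = terms or default_mood_terms()
    df = log.df
    if log.is_annotated:
        msd_flag = df["msd_flag"].to_numpy()
    else:
        msd_flag = np.array([is_msd_query(t, lex)[0] for t in df["query_text"]])
    msd_users = set(df.loc[msd_flag, "user_id"])
    if not msd_users:
        return ComorbidResult(0, 0, float("nan"))
    sub = df[df["user_id"].isin(msd_users)]
    mood_users: set[str] = set()
    com_users: set[str] = set()
    disorder = [tuple(tokenize(t)) for t in terms.disorder_terms]
    comorbid = [tuple(tokenize(t)) for t in terms.comorbid_terms]
    for text, uid in zip(sub["query_text"], sub["user_id"]):
        tokens = tokenize(text)
        if uid not in mood_users and any(_contains_phrase(tokens, p) for p in disorder):
            mood_users.add(uid)
        if uid not in com_users and any(_contains_phrase(tokens, p) for p in comorbid):
            com_users.add(uid)
    n_mood, n_com = len(mood_users), len(com_users)
    ratio = n_mood / n_com if n_com else float("nan")
    return ComorbidResult(n_mood, n_com, ratio)


def annotate(
    log: SearchLog,
    drug_lex: DrugLexicon | None = None,
    cat_lex: CategoryLexicon | None = None,
) -> SearchLog:
    """Append per-query annotation columns to a log.

    Added columns: ``msd_flag`` (bool), ``matched`` (drug name /
    "stabilizer-phrase" / "lithium" / ""), ``drug_names`` (all specific
    names, ';'-joined), ``categories`` (sorted category names,
    ';'-joined). Classification runs once per unique query text, so the
    result is identical to applying the per-query functions row by row.
    """
    drug_lex = drug_lex or default_drug_lexicon()
    cat_lex = cat_lex or default_category_lexicon()
    texts = log.df["query_text"].to_numpy()
    uniq, inverse = np.unique(texts, return_inverse=True)

    msd_flag_u = np.zeros(len(uniq), dtype=bool)
    matched_u = np.empty(len(uniq), dtype=object)
    names_u = np.empty(len(uniq), dtype=object)
    cats_u = np.empty(len(uniq), dtype=object)
    for i, text in enumerate(uniq):
        flag, matched = is_msd_query(text, drug_lex)
        msd_flag_u[i] = flag
        matched_u[i] = matched or ""
        names_u[i] = ";".join(drug_names_in(text, drug_lex)) if flag else ""
        cats_u[i] = ";".join(sorted(classify_query(text, cat_lex)))

    df = log.df.copy()
    df["msd_flag"] = msd_flag_u[inverse]
    df["matched"] = matched_u[inverse]
    df["drug_names"] = names_u[inverse]
    df["categories"] = cats_u[inverse]
    return SearchLog(df=df, window=log.window, n_malformed=log.n_malformed)


def category_membership(log: SearchLog, category: str) -> np.ndarray:
    """Boolean array: does each annotated query belong to ``category``."""
    log.require_annotated()
    pat = rf"(?:^|;){re.escape(category)}(?:;|$)"
    return log.df["categories"].str.contains(pat, regex=True).to_numpy()
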