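"""Lexical items and the built-in 16-noun / 16-verb stimulus lexicon.

Nouns name individuals practicing a sport or playing music (8 per
category); verbs are transitive and denote either physical contact or
perception (8 per category). All perception verbs are
experiencer-subject verbs: in deep structure the perceiver fills the
subject slot and the perceived entity the object slot, regardless of
grammatical voice.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InvalidLexiconError

NOUN_CATEGORIES = ("sport", "music")
VERB_CATEGORIES = ("contact", "perception")


@dataclass(frozen=True, order=True)
class LexicalItem:
    """A single lemma with its word class and semantic category."""

    lemma: str
    word_class: str  # "noun" | "verb"
    category: str  # sport|music for nouns, contact|perception for verbs
    log_freq: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.word_class == "noun" and self.category not in NOUN_CATEGORIES:
            raise InvalidLexiconError(
                f"noun {self.lemma!r} has category {self.category!r}, "
                f"expected one of {NOUN_CATEGORIES}"
            )
        if self.word_class == "verb" and self.category not in VERB_CATEGORIES:
            raise InvalidLexiconError(
                f"verb {self.lemma!r} has category {self.category!r}, "
                f"expected one of {VERB_CATEGORIES}"
            )

    @property
    def length_chars(self) -> int:
        return len(self.lemma)


@dataclass(frozen=True)
class Lexicon:
    """An ordered collection of nouns and verbs."""

    nouns: tuple[LexicalItem, ...]
    verbs: tuple[LexicalItem, ...]

    def __post_init__(self) -> None:
        lemmas = [it.lemma for it in self.nouns + self.verbs]
        if len(set(lemmas)) != len(lemmas):
            dups = sorted({x for x in lemmas if lemmas.count(x) > 1})
            raise InvalidLexiconError(f"duplicate lemmas in lexicon: {dups}")

    def noun(self, lemma: str) -> LexicalItem:
        return self._lookup(lemma, self.nouns, "noun")

    def verb(self, lemma: str) -> LexicalItem:
        return self._lookup(lemma, self.verbs, "verb")

    @staticmethod
    def _lookup(lemma: str, items: tuple[LexicalItem, ...], kind: str) -> LexicalItem:
        for it in items:
            if it.lemma == lemma:
                return it
        raise InvalidLexiconError(f"unknown {kind} lemma {lemma!r}")

    def nouns_of(self, category: str) -> list[LexicalItem]:
        return [n for n in self.nouns if n.category == category]

    def verbs_of(self, category: str) -> list[LexicalItem]:
        return [v for v in self.verbs if v.category == category]


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Load a lexicon TSV (columns lemma, word_class, category[, log_freq]).

    With no argument, loads the built-in stimulus lexicon. When loaded from
    the built-in table, the lexicon carries 8 nouns per noun category and
    8 verbs per verb category.
    """
    if path is None:
        ref = importlib.resources.files("sentencode").joinpath(
            "data/stimulus_lexicon.tsv"
        )
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"lemma", "word_class", "category"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidLexiconError(f"lexicon file missing columns: {sorted(missing)}")

    def _make(row: pd.Series) -> LexicalItem:
        lf = row.get("log_freq")
        return LexicalItem(
            lemma=str(row["lemma"]),
            word_class=str(row["word_class"]),
            category=str(row["category"]),
            log_freq=None if lf is None or pd.isna(lf) else float(lf),
        )

    nouns = tuple(_make(r) for _, r in df[df.word_class == "noun"].iterrows())
    verbs = tuple(_make(r) for _, r in df[df.word_class == "verb"].iterrows())
    return Lexicon(nouns=nouns, verbs=verbs)


def length_stats(items: list[LexicalItem]) -> tuple[float, float]:
    """Mean and population SD (denominator n) of lemma character counts."""
    if not items:
        raise InvalidLexiconError("length_stats of an empty item list")
    import numpy as np

    lengths = np.array([it.length_chars for it in items], dtype=float)
    return float(lengths.mean()), float(lengths.std(ddof=0))
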