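"""Binary sentence featurization for the seven encoding models.

Each model describes a sentence at a different level of relational
specificity:

================================  ====  =============================================
model                              p    predictor meaning
================================  ====  =============================================
bag_of_nouns_cat                    2   noun semantic category present (M, A)
broad_roles                         8   noun category x broad thematic role
narrow_roles                       64   noun category x verb-specific role
bag_of_verbs                       16   verb identity
bag_of_nouns_specific              16   noun identity
noun_specific_broad_roles          64   noun identity x broad thematic role
full_relational                   512   noun identity x verb-specific role
================================  ====  =============================================

Thematic roles are deep roles, assigned from (agent, patient, verb)
only — never from voice or surface word order. Contact verbs take
agent/patient roles; perception verbs are experiencer-subject, so the
deep-subject noun is the experiencer and the deep-object noun the
stimulus. "M" abbreviates the musician noun category, "A" the athlete
(sport) category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import SentenceSpec
from .errors import IdCollisionError, UnknownItemError, UnknownModelError
from .lexicon import Lexicon, load_lexicon

MODEL_NAMES = (
    "bag_of_nouns_cat",
    "broad_roles",
    "narrow_roles",
    "bag_of_verbs",
    "bag_of_nouns_specific",
    "noun_specific_broad_roles",
    "full_relational",
)

#: Expected predictor counts per model.
PREDICTOR_COUNTS = {
    "bag_of_nouns_cat": 2,
    "broad_roles": 8,
    "narrow_roles": 64,
    "bag_of_verbs": 16,
    "bag_of_nouns_specific": 16,
    "noun_specific_broad_roles": 64,
    "full_relational": 512,
}

_CAT_LETTER = {"music": "M", "sport": "A"}
_BROAD_ROLES = ("agent", "patient", "experiencer", "stimulus")


def _deep_roles(verb_category: str) -> tuple[str, str]:
    """(deep-subject role, deep-object role) for a verb category."""
    if verb_category == "contact":
        return ("agent", "patient")
    if verb_category == "perception":
        return ("experiencer", "stimulus")
    raise UnknownItemError(f"unknown verb category {verb_category!r}")


@dataclass(frozen=True)
class EncodingModelSpec:
    """A named encoding model with its ordered predictor labels."""

    name: str
    predictor_labels: tuple[str, ...]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise UnknownModelError(f"unknown encoding model {self.name!r}")
        if len(set(self.predictor_labels)) != len(self.predictor_labels):
            raise UnknownModelError(f"duplicate predictor labels in {self.name!r}")
        expected = PREDICTOR_COUNTS[self.name]
        if len(self.predictor_labels) != expected:
            raise UnknownModelError(
                f"model {self.name!r} must have {expected} predictors, "
                f"got {len(self.predictor_labels)}"
            )
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.predictor_labels)}
        )

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_labels)

    def index(self, label: str) -> int:
        return self._index[label]


def get_model(name: str, lexicon: Lexicon | None = None) -> EncodingModelSpec:
    """Build the EncodingModelSpec for one of the seven models over a lexicon."""
    lex = lexicon or load_lexicon()
    nouns = [n.lemma for n in lex.nouns]
    verbs = list(lex.verbs)
    if name == "bag_of_nouns_cat":
        labels = ("M", "A")
    elif name == "broad_roles":
        labels = tuple(
            f"{c}-as-{role}" for c in ("M", "A") for role in _BROAD_ROLES
        )
    elif name == "narrow_roles":
        labels = tuple(
            f"{c}-as-{v.lemma}-{role}"
            for v in verbs
            for c in ("M", "A")
            for role in _deep_roles(v.category)
        )
    elif name == "bag_of_verbs":
        labels = tuple(v.lemma for v in verbs)
    elif name == "bag_of_nouns_specific":
        labels = tuple(nouns)
    elif name == "noun_specific_broad_roles":
        labels = tuple(f"{n}-as-{role}" for n in nouns for role in _BROAD_ROLES)
    elif name == "full_relational":
        labels = tuple(
            f"{n}-as-{v.lemma}-{role}"
            for n in nouns
            for v in verbs
            for role in _deep_roles(v.category)
        )
    else:
        raise UnknownModelError(f"unknown encoding model {name!r}")
    return EncodingModelSpec(name=name, predictor_labels=labels)


def predictor_count(model: str | EncodingModelSpec) -> int:
    """Number of predictors of an encoding model."""
    name = model.name if isinstance(model, EncodingModelSpec) else model
    if name not in PREDICTOR_COUNTS:
        raise UnknownModelError(f"unknown encoding model {name!r}")
    return PREDICTOR_COUNTS[name]


def featurize(sentence: SentenceSpec, model: EncodingModelSpec) -> np.ndarray:
    """Binary predictor vector of a sentence under an encoding model.

    Depends only on (agent, patient, verb, verb category); active and
    passive realizations of the same deep structure featurize identically.
    """
    vec = np.zeros(model.n_predictors, dtype=np.int8)
    a, p, v = sentence.agent, sentence.patient, sentence.verb
    subj_role, obj_role = _deep_roles(v.category)
    try:
        if model.name == "bag_of_nouns_cat":
            vec[model.index(_CAT_LETTER[a.category])] = 1
            vec[model.index(_CAT_LETTER[p.category])] = 1
        elif model.name == "broad_roles":
            vec[model.index(f"{_CAT_LETTER[a.category]}-as-{subj_role}")] = 1
            vec[model.index(f"{_CAT_LETTER[p.category]}-as-{obj_role}")] = 1
        elif model.name == "narrow_roles":
            vec[model.index(f"{_CAT_LETTER[a.category]}-as-{v.lemma}-{subj_role}")] = 1
            vec[model.index(f"{_CAT_LETTER[p.category]}-as-{v.lemma}-{obj_role}")] = 1
        elif model.name == "bag_of_verbs":
            vec[model.index(v.lemma)] = 1
        elif model.name == "bag_of_nouns_specific":
            vec[model.index(a.lemma)] = 1
            vec[model.index(p.lemma)] = 1
        elif model.name == "noun_specific_broad_roles":
            vec[model.index(f"{a.lemma}-as-{subj_role}")] = 1
            vec[model.index(f"{p.lemma}-as-{obj_role}")] = 1
        elif model.name == "full_relational":
            vec[model.index(f"{a.lemma}-as-{v.lemma}-{subj_role}")] = 1
            vec[model.index(f"{p.lemma}-as-{v.lemma}-{obj_role}")] = 1
    except KeyError as exc:
        raise UnknownItemError(
            f"sentence uses out-of-lexicon item: {exc.args[0]!r}"
        ) from None
    return vec


@dataclass(frozen=True)
class DesignMatrix:
    """Sentences x predictors binary matrix for one encoding model."""

    sentence_ids: tuple
    model: EncodingModelSpec
    entries: np.ndarray

    def __post_init__(self) -> None:
        if self.entries.shape != (len(self.sentence_ids), self.model.n_predictors):
            raise IdCollisionError("entries shape does not match ids x predictors")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            index=list(self.sentence_ids),
            columns=list(self.model.predictor_labels),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sentence_id")


def build_design_matrix(
    sentences: list[SentenceSpec],
    model: str | EncodingModelSpec,
    sentence_ids: list | None = None,
    lexicon: Lexicon | None = None,
) -> DesignMatrix:
    """Stack featurize() over a sentence list into a DesignMatrix."""
    if not sentences:
        raise IdCollisionError("cannot build a design matrix from zero sentences")
    spec = model if isinstance(model, EncodingModelSpec) else get_model(model, lexicon)
    ids = tuple(sentence_ids) if sentence_ids is not None else tuple(range(len(sentences)))
    if len(set(ids)) != len(ids):
        raise IdCollisionError("duplicate sentence ids")
    if len(ids) != len(sentences):
        raise IdCollisionError("sentence_ids length does not match sentences")
    if spec.name == "full_relational" and len(sentences) < spec.n_predictors:
        warnings.warn(
            "full_relational has more predictors than sentences; weight fits "
            "will be rank-deficient (minimum-norm solutions)",
            stacklevel=2,
        )
    entries = np.stack([featurize(s, spec) for s in sentences])
    return DesignMatrix(sentence_ids=ids, model=spec, entries=entries)
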