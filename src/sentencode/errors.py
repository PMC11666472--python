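"""Exception hierarchy for the sentencode pipeline."""


class SentencodeError(Exception):
    """Base class for all package errors."""


class InvalidLexiconError(SentencodeError):
    """The lexicon violates a structural requirement (duplicates, wrong counts)."""


class ConstraintInfeasibleError(SentencodeError):
    """A balanced stimulus set cannot exist under the requested constraints.

    The message names the violated constraint.
    """


class BalancingError(SentencodeError):
    """Voice/word-order assignment cannot be balanced within a cell."""


class ScheduleError(SentencodeError):
    """Run scheduling received inputs with the wrong composition."""


class UnknownItemError(SentencodeError):
    """A sentence references a lemma outside the lexicon."""


class UnknownModelError(SentencodeError):
    """An encoding-model name is not one of the defined specifications."""


class IdCollisionError(SentencodeError):
    """Duplicate sentence identifiers in a design-matrix build."""


class DatasetIOError(SentencodeError):
    """A beta-map dataset directory is missing or malformed; names the file."""


class FoldError(SentencodeError):
    """Too few runs or usable sentences to cross-validate."""


class EmptySummaryError(SentencodeError):
    """A design summary was requested for an empty stimulus set."""
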