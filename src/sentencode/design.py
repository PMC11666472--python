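"""Balanced stimulus design for the sentence-production experiment.

The experiment crosses 16 nouns (8 "sport", 8 "music") with 16 transitive
verbs (8 "contact", 8 "perception") into noun-verb-noun sentences with
distinct agent and patient. From the full pool (16 x 15 x 16 = 3,840
sentences) a balanced subset is selected such that

* every verb is used equally often,
* every noun occurs equally often as agent and as patient,
* every (noun, verb) combination occurs at least once in each role,
* each of the 8 sentence-level category patterns
  (agent category x verb category x patient category) occurs equally often,
* repeated unordered noun pairs are kept to a minimum.

Half the selected sentences are assigned active voice; the passive half is
split between the two word orders Dutch allows for passives (verb-final
"de bokser wordt door de muzikant herkend" vs. verb-medial "de bokser
wordt herkend door de muzikant"). Voice assignment is balanced within
every category pattern. Finally the sentences are scheduled into 6 runs
of 60 trials (42 production + 6 question + 12 filler) with near-uniform
noun/verb distribution across runs.

The selection algorithm is constructive: for each verb, agent and patient
multisets are built that contain every noun once plus category-balanced
extras, and are then paired within category blocks by Hungarian assignment
with costs that forbid agent = patient and penalize noun-pair repeats.
This meets every balance constraint exactly for any seed.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import (
    BalancingError,
    ConstraintInfeasibleError,
    EmptySummaryError,
    InvalidLexiconError,
    ScheduleError,
)
from .lexicon import LexicalItem, Lexicon, length_stats

VOICES = ("active", "passive")
PASSIVE_ORDERS = ("verb_final", "verb_medial", "not_applicable")
TRIAL_TYPES = ("production", "question", "filler")

_BIG = 1e9  # assignment cost that encodes an infeasible pairing


@dataclass(frozen=True)
class SentenceSpec:
    """One noun-verb-noun sentence in deep-structure terms.

    ``agent`` and ``patient`` are deep roles: for perception verbs the
    ``agent`` slot holds the experiencer and the ``patient`` slot the
    stimulus, regardless of voice.
    """

    agent: LexicalItem
    patient: LexicalItem
    verb: LexicalItem
    voice: str = "active"
    passive_order: str = "not_applicable"
    trial_type: str = "production"

    def __post_init__(self) -> None:
        if self.agent.lemma == self.patient.lemma:
            raise ConstraintInfeasibleError(
                f"agent and patient must differ (got {self.agent.lemma!r} twice)"
            )
        if self.voice not in VOICES:
            raise ValueError(f"invalid voice {self.voice!r}")
        if self.passive_order not in PASSIVE_ORDERS:
            raise ValueError(f"invalid passive_order {self.passive_order!r}")
        if (self.voice == "active") != (self.passive_order == "not_applicable"):
            raise ValueError(
                "passive_order must be 'not_applicable' iff voice is 'active'"
            )
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"invalid trial_type {self.trial_type!r}")

    @property
    def category_pattern(self) -> tuple[str, str, str]:
        """(agent category, verb category, patient category)."""
        return (self.agent.category, self.verb.category, self.patient.category)

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.agent.lemma, self.verb.lemma, self.patient.lemma)


@dataclass(frozen=True)
class StimulusSet:
    """Sentences scheduled into runs; ``run_of[i]`` is the run (1-based) of
    ``sentences[i]``; trials are ordered by run, then within-run position."""

    sentences: tuple[SentenceSpec, ...]
    run_of: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sentences) != len(self.run_of):
            raise ScheduleError("sentences and run_of must be aligned")

    @property
    def n_runs(self) -> int:
        return max(self.run_of) if self.run_of else 0

    def run(self, r: int) -> list[SentenceSpec]:
        return [s for s, rr in zip(self.sentences, self.run_of) if rr == r]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        idx_in_run: Counter[int] = Counter()
        for s, r in zip(self.sentences, self.run_of):
            idx_in_run[r] += 1
            rows.append(
                {
                    "run": r,
                    "trial_index": idx_in_run[r],
                    "trial_type": s.trial_type,
                    "agent": s.agent.lemma,
                    "verb": s.verb.lemma,
                    "patient": s.patient.lemma,
                    "voice": s.voice,
                    "passive_order": s.passive_order,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, lexicon: Lexicon) -> "StimulusSet":
        df = pd.read_csv(path, sep="\t")
        sentences, runs = [], []
        for _, row in df.iterrows():
            sentences.append(
                SentenceSpec(
                    agent=_lookup_or_stub(lexicon, row["agent"], "noun"),
                    patient=_lookup_or_stub(lexicon, row["patient"], "noun"),
                    verb=_lookup_or_stub(lexicon, row["verb"], "verb"),
                    voice=row["voice"],
                    passive_order=row["passive_order"],
                    trial_type=row["trial_type"],
                )
            )
            runs.append(int(row["run"]))
        return cls(sentences=tuple(sentences), run_of=tuple(runs))


def _lookup_or_stub(lexicon: Lexicon, lemma: str, word_class: str) -> LexicalItem:
    # Fillers may use out-of-lexicon lemmas; stub them (never analyzed).
    try:
        return lexicon.noun(lemma) if word_class == "noun" else lexicon.verb(lemma)
    except InvalidLexiconError:
        cat = "sport" if word_class == "noun" else "contact"
        return LexicalItem(lemma=str(lemma), word_class=word_class, category=cat)


# ---------------------------------------------------------------------------
# Pool enumeration
# ---------------------------------------------------------------------------


def enumerate_pool(
    nouns: list[LexicalItem], verbs: list[LexicalItem]
) -> list[SentenceSpec]:
    """All ordered (agent, patient, verb) triples with agent != patient.

    For the built-in lexicon this yields 16 x 15 x 16 = 3,840 sentences.
    """
    lemmas = [it.lemma for it in list(nouns) + list(verbs)]
    if len(set(lemmas)) != len(lemmas):
        raise InvalidLexiconError("duplicate lemmas in the input lexicon")
    pool = []
    for a in nouns:
        for p in nouns:
            if a.lemma == p.lemma:
                continue
            for v in verbs:
                pool.append(SentenceSpec(agent=a, patient=p, verb=v))
    return pool


# ---------------------------------------------------------------------------
# Balanced selection
# ---------------------------------------------------------------------------


def select_balanced_set(
    pool: list[SentenceSpec], n_target: int = 288, seed: int = 0
) -> list[SentenceSpec]:
    """Select ``n_target`` sentences satisfying all balance constraints exactly.

    See the module docstring for the constraint list and algorithm sketch.
    Raises :class:`ConstraintInfeasibleError` naming the violated constraint
    when no balanced set of the requested size can exist.
    """
    rng = np.random.default_rng(seed)
    nouns = sorted({s.agent for s in pool} | {s.patient for s in pool})
    verbs = sorted({s.verb for s in pool})
    n_nouns, n_verbs = len(nouns), len(verbs)
    if n_target % n_verbs:
        raise ConstraintInfeasibleError(
            f"verb balance: n_target={n_target} not divisible by {n_verbs} verbs"
        )
    if n_target % n_nouns:
        raise ConstraintInfeasibleError(
            f"noun-role balance: n_target={n_target} not divisible by {n_nouns} nouns"
        )
    if n_target % 8:
        raise ConstraintInfeasibleError(
            f"category-pattern balance: n_target={n_target} not divisible by 8"
        )
    by_cat_n = {c: [n for n in nouns if n.category == c] for c in ("sport", "music")}
    by_cat_v = {
        c: [v for v in verbs if v.category == c] for c in ("contact", "perception")
    }
    if len(by_cat_n["sport"]) != len(by_cat_n["music"]):
        raise ConstraintInfeasibleError("noun categories must be the same size")
    if len(by_cat_v["contact"]) != len(by_cat_v["perception"]):
        raise ConstraintInfeasibleError("verb categories must be the same size")
    a = len(by_cat_n["sport"])  # nouns per category
    b = len(by_cat_v["contact"])  # verbs per category
    k = n_target // n_verbs  # sentences per verb (= uses per noun per role)
    if k < n_nouns:
        raise ConstraintInfeasibleError(
            "noun-verb-role coverage: each verb has "
            f"{k} sentences but must host all {n_nouns} nouns in each role"
        )
    if k % 2:
        raise ConstraintInfeasibleError(
            f"per-verb category balance: {k} sentences per verb cannot split "
            "evenly between agent noun categories"
        )
    n_extra = (k - n_nouns) // 2  # extras per verb per role per noun category
    if (b * (k - n_nouns)) % a:
        raise ConstraintInfeasibleError(
            "per-noun balance: extra slots do not distribute evenly over nouns"
        )
    extras_per_noun = b * (k - n_nouns) // a  # per role

    # Which extra nouns each verb receives, per (role, noun category):
    # every noun must appear exactly `extras_per_noun` times per role.
    extras: dict[tuple[str, str], list[list[LexicalItem]]] = {}
    for role in ("agent", "patient"):
        for cat in ("sport", "music"):
            extras[(role, cat)] = _deal_extras(
                by_cat_n[cat], n_verbs, n_extra, extras_per_noun * a // a, rng
            )

    # Same-category pair quota x_v per verb: within each verb category the
    # (sport, vcat, sport) pattern needs n_target/8 sentences in total.
    quota = n_target // 8
    sentences: list[SentenceSpec] = []
    pair_counts: Counter[frozenset[str]] = Counter()
    used_triples: set[tuple[str, str, str]] = set()
    verb_order = list(range(n_verbs))
    rng.shuffle(verb_order)
    x_of: dict[str, int] = {}
    for vcat in ("contact", "perception"):
        vs = by_cat_v[vcat]
        base, rem = divmod(quota, len(vs))
        bonus = rng.permutation(len(vs)) < rem
        for i, v in enumerate(vs):
            x_of[v.lemma] = base + int(bonus[i])

    for vi in verb_order:
        v = verbs[vi]
        x = x_of[v.lemma]
        if x > k // 2:
            raise ConstraintInfeasibleError(
                "category-pattern balance: per-verb same-category quota "
                f"{x} exceeds the {k // 2} same-category agent slots"
            )
        agents = {
            c: list(by_cat_n[c]) + extras[("agent", c)][vi] for c in ("sport", "music")
        }
        patients = {
            c: list(by_cat_n[c]) + extras[("patient", c)][vi]
            for c in ("sport", "music")
        }
        sentences.extend(
            _pair_for_verb(v, agents, patients, x, pair_counts, used_triples, rng)
        )

    order = rng.permutation(len(sentences))
    return [sentences[i] for i in order]


def _deal_extras(
    cat_nouns: list[LexicalItem],
    n_verbs: int,
    n_extra: int,
    _unused: int,
    rng: np.random.Generator,
) -> list[list[LexicalItem]]:
    """Deal ``n_extra`` extra nouns to each verb so every noun gets an equal
    total, with no duplicate within a verb."""
    a = len(cat_nouns)
    total = n_verbs * n_extra
    per_noun = total // a
    if n_extra == 0:
        return [[] for _ in range(n_verbs)]
    for _ in range(200):
        deck: list[LexicalItem] = [n for n in cat_nouns for _ in range(per_noun)]
        rng.shuffle(deck)
        chunks = [deck[i * n_extra : (i + 1) * n_extra] for i in range(n_verbs)]
        if all(len({n.lemma for n in ch}) == len(ch) for ch in chunks):
            return chunks
    raise ConstraintInfeasibleError(
        "per-noun balance: could not deal extra noun slots without duplicates"
    )


def _pair_for_verb(
    verb: LexicalItem,
    agents: dict[str, list[LexicalItem]],
    patients: dict[str, list[LexicalItem]],
    x: int,
    pair_counts: Counter,
    used_triples: set,
    rng: np.random.Generator,
) -> list[SentenceSpec]:
    """Pair this verb's agent and patient multisets into sentences.

    ``x`` same-category pairs per noun category; the remainder crosses
    categories. Each category block is solved by Hungarian assignment with
    infinite cost on agent == patient and on already-used triples, and a
    repeat-pair penalty otherwise.
    """
    half = len(agents["sport"])
    for attempt in range(60):
        a_s = list(agents["sport"])
        a_m = list(agents["music"])
        p_s = list(patients["sport"])
        p_m = list(patients["music"])
        for lst in (a_s, a_m, p_s, p_m):
            rng.shuffle(lst)
        blocks = [
            (a_s[:x], p_s[:x]),  # sport-sport
            (a_s[x:], p_m[: half - x]),  # sport-music
            (a_m[: half - x], p_s[x:]),  # music-sport
            (a_m[half - x :], p_m[half - x :]),  # music-music
        ]
        out: list[SentenceSpec] = []
        new_pairs: Counter = Counter()
        new_triples: set = set()
        ok = True
        for ag, pt in blocks:
            if not ag:
                continue
            cost = np.empty((len(ag), len(pt)))
            for i, an in enumerate(ag):
                for j, pn in enumerate(pt):
                    trip = (an.lemma, verb.lemma, pn.lemma)
                    if an.lemma == pn.lemma or trip in used_triples or trip in new_triples:
                        cost[i, j] = _BIG
                    else:
                        cost[i, j] = pair_counts[frozenset((an.lemma, pn.lemma))] + new_pairs[
                            frozenset((an.lemma, pn.lemma))
                        ]
            cost += rng.uniform(0, 1e-6, cost.shape)  # random tie-break
            ri, ci = linear_sum_assignment(cost)
            if cost[ri, ci].max() >= _BIG:
                ok = False
                break
            # Duplicated multiset entries can yield the same triple twice
            # inside one assignment; reject and reshuffle if so.
            trips = [(ag[i].lemma, verb.lemma, pt[j].lemma) for i, j in zip(ri, ci)]
            if len(set(trips)) != len(trips):
                ok = False
                break
            for i, j in zip(ri, ci):
                an, pn = ag[i], pt[j]
                out.append(SentenceSpec(agent=an, patient=pn, verb=verb))
                new_pairs[frozenset((an.lemma, pn.lemma))] += 1
                new_triples.add((an.lemma, verb.lemma, pn.lemma))
        if ok:
            pair_counts.update(new_pairs)
            used_triples.update(new_triples)
            return out
    raise ConstraintInfeasibleError(
        f"pairing: no feasible agent-patient matching for verb {verb.lemma!r}"
    )


# ---------------------------------------------------------------------------
# Voice assignment
# ---------------------------------------------------------------------------


def assign_voice_and_order(
    sentences: list[SentenceSpec], seed: int = 0
) -> list[SentenceSpec]:
    """Assign voice 50/50 and split passives into the two word orders.

    Balance is enforced *within* every category pattern, which requires each
    pattern cell to have a size divisible by 4 (half active; the passive half
    split equally between verb-final and verb-medial order).
    """
    if not sentences:
        return []
    if len(sentences) % 2:
        raise BalancingError("voice balance requires an even sentence count")
    rng = np.random.default_rng(seed)
    cells: dict[tuple[str, str, str], list[int]] = {}
    for i, s in enumerate(sentences):
        cells.setdefault(s.category_pattern, []).append(i)
    out: list[SentenceSpec | None] = [None] * len(sentences)
    for pattern, idx in cells.items():
        if len(idx) % 4:
            raise BalancingError(
                f"cell {pattern} has {len(idx)} sentences; voice/order balance "
                "needs a multiple of 4"
            )
        idx = list(idx)
        rng.shuffle(idx)
        half = len(idx) // 2
        quarter = half // 2
        for i in idx[:half]:
            out[i] = replace(
                sentences[i], voice="active", passive_order="not_applicable"
            )
        for i in idx[half : half + quarter]:
            out[i] = replace(sentences[i], voice="passive", passive_order="verb_final")
        for i in idx[half + quarter :]:
            out[i] = replace(sentences[i], voice="passive", passive_order="verb_medial")
    return [s for s in out if s is not None]


# ---------------------------------------------------------------------------
# Question split, fillers, run scheduling
# ---------------------------------------------------------------------------


def split_questions(
    sentences: list[SentenceSpec], n_questions: int = 36, seed: int = 0
) -> tuple[list[SentenceSpec], list[SentenceSpec]]:
    """Split a balanced set into production and question trials.

    Question sentences are drawn from the same balanced pool (stratified over
    category patterns) so the joint balance identities hold.
    """
    rng = np.random.default_rng(seed)
    cells: dict[tuple[str, str, str], list[int]] = {}
    for i, s in enumerate(sentences):
        cells.setdefault(s.category_pattern, []).append(i)
    patterns = sorted(cells)
    base, rem = divmod(n_questions, len(patterns))
    bonus = rng.permutation(len(patterns)) < rem
    q_idx: set[int] = set()
    for pi, pattern in enumerate(patterns):
        take = base + int(bonus[pi])
        q_idx.update(rng.choice(cells[pattern], size=take, replace=False).tolist())
    production, questions = [], []
    for i, s in enumerate(sentences):
        if i in q_idx:
            questions.append(replace(s, trial_type="question"))
        else:
            production.append(s)
    return production, questions


_AUX_NOUNS = [
    "man", "vrouw", "jongen", "buurman", "leraar", "dokter", "kapper", "bakker",
]
_AUX_VERBS = ["groeten", "helpen", "roepen", "volgen", "zoeken", "horen"]


def make_fillers(n: int = 72, seed: int = 0) -> list[SentenceSpec]:
    """Free-form filler placeholders from an auxiliary lexicon.

    Filler content increases surface variability only and never enters any
    analysis; category fields are dummy values.
    """
    rng = np.random.default_rng(seed)
    nouns = [
        LexicalItem(lemma=w, word_class="noun", category="sport") for w in _AUX_NOUNS
    ]
    verbs = [
        LexicalItem(lemma=w, word_class="verb", category="contact") for w in _AUX_VERBS
    ]
    out = []
    for i in range(n):
        a, p = rng.choice(len(nouns), size=2, replace=False)
        v = rng.integers(len(verbs))
        voice = "active" if i % 2 == 0 else "passive"
        order = "not_applicable" if voice == "active" else (
            "verb_final" if i % 4 == 1 else "verb_medial"
        )
        out.append(
            SentenceSpec(
                agent=nouns[a],
                patient=nouns[p],
                verb=verbs[v],
                voice=voice,
                passive_order=order,
                trial_type="filler",
            )
        )
    return out


def schedule_runs(
    production: list[SentenceSpec],
    fillers: list[SentenceSpec],
    questions: list[SentenceSpec],
    seed: int = 0,
    n_runs: int = 6,
    max_imbalance: int = 2,
) -> StimulusSet:
    """Schedule trials into runs (default 6 x 60 = 42 production + 6 question
    + 12 filler) with near-uniform noun/verb distribution across runs.

    Per-verb counts are split exactly across runs; per-noun-per-role counts
    are balanced greedily with local swap repair until the max-min count
    difference across runs is at most ``max_imbalance``.
    """
    rng = np.random.default_rng(seed)
    n_prod, n_q, n_f = len(production), len(questions), len(fillers)
    for name, count, per_run in (
        ("production", n_prod, None),
        ("question", n_q, None),
        ("filler", n_f, None),
    ):
        if count % n_runs:
            raise ScheduleError(
                f"{name} count {count} not divisible by {n_runs} runs"
            )
    combined = production + questions
    verb_counts = Counter(s.verb.lemma for s in combined)
    if any(c % n_runs for c in verb_counts.values()):
        raise ScheduleError("per-verb counts must divide evenly across runs")
    target = {v: c // n_runs for v, c in verb_counts.items()}
    q_per_run = n_q // n_runs

    # Phase 1: place questions, q_per_run per run, at most `target` per verb.
    for _ in range(200):
        q_assign: dict[int, int] = {}
        room = {r: dict(target) for r in range(n_runs)}
        qcount = {r: 0 for r in range(n_runs)}
        order = rng.permutation(n_q)
        ok = True
        for qi in order:
            v = questions[qi].verb.lemma
            options = [
                r
                for r in range(n_runs)
                if qcount[r] < q_per_run and room[r][v] > 0
            ]
            if not options:
                ok = False
                break
            r = min(options, key=lambda r: (qcount[r], -room[r][v]))
            q_assign[qi] = r
            qcount[r] += 1
            room[r][v] -= 1
        if ok:
            break
    if not ok:
        raise ScheduleError("could not distribute question trials across runs")

    # Phase 2: per verb, fill remaining run slots with production sentences,
    # greedily balancing noun-role counts per run.
    agent_ct = [Counter() for _ in range(n_runs)]
    patient_ct = [Counter() for _ in range(n_runs)]
    p_assign: dict[int, int] = {}
    by_verb: dict[str, list[int]] = {}
    for i, s in enumerate(production):
        by_verb.setdefault(s.verb.lemma, []).append(i)
    for qi, r in q_assign.items():
        agent_ct[r][questions[qi].agent.lemma] += 1
        patient_ct[r][questions[qi].patient.lemma] += 1
    for v in rng.permutation(sorted(by_verb)):
        idxs = by_verb[v]
        rng.shuffle(idxs)
        slots: list[int] = []
        for r in range(n_runs):
            used = sum(1 for qi, rr in q_assign.items() if rr == r and questions[qi].verb.lemma == v)
            slots.extend([r] * (target[v] - used))
        rng.shuffle(slots)
        for i in idxs:
            s = production[i]
            r = min(
                set(slots),
                key=lambda r: agent_ct[r][s.agent.lemma]
                + patient_ct[r][s.patient.lemma]
                + rng.uniform(0, 1e-3),
            )
            slots.remove(r)
            p_assign[i] = r
            agent_ct[r][s.agent.lemma] += 1
            patient_ct[r][s.patient.lemma] += 1

    _repair_noun_balance(
        production, p_assign, agent_ct, patient_ct, n_runs, max_imbalance, rng
    )

    # Fillers: round-robin.
    f_assign = {i: i % n_runs for i in range(n_f)}

    per_run: dict[int, list[SentenceSpec]] = {r: [] for r in range(n_runs)}
    for i, r in p_assign.items():
        per_run[r].append(production[i])
    for qi, r in q_assign.items():
        per_run[r].append(questions[qi])
    for fi, r in f_assign.items():
        per_run[r].append(fillers[fi])
    sentences: list[SentenceSpec] = []
    runs: list[int] = []
    for r in range(n_runs):
        order = rng.permutation(len(per_run[r]))
        for j in order:
            sentences.append(per_run[r][j])
            runs.append(r + 1)
    return StimulusSet(sentences=tuple(sentences), run_of=tuple(runs))


def _repair_noun_balance(
    production: list[SentenceSpec],
    p_assign: dict[int, int],
    agent_ct: list[Counter],
    patient_ct: list[Counter],
    n_runs: int,
    max_imbalance: int,
    rng: np.random.Generator,
) -> None:
    """Swap same-verb production sentences between runs until per-noun-role
    counts differ by at most ``max_imbalance`` across runs."""

    def worst() -> tuple[int, str, str] | None:
        worst_item = None
        worst_spread = max_imbalance
        for role, cts in (("agent", agent_ct), ("patient", patient_ct)):
            lemmas = sorted(set().union(*[set(c) for c in cts]))
            for lem in lemmas:
                vals = [c[lem] for c in cts]
                spread = max(vals) - min(vals)
                if spread > worst_spread:
                    worst_spread = spread
                    worst_item = (spread, role, lem)
        return worst_item

    for _ in range(5000):
        item = worst()
        if item is None:
            return
        _, role, lem = item
        cts = agent_ct if role == "agent" else patient_ct
        vals = [c[lem] for c in cts]
        r_hi = int(np.argmax(vals))
        r_lo = int(np.argmin(vals))
        # Find a sentence with this noun in this role in r_hi, and a same-verb
        # partner in r_lo without it, and swap their runs.
        cands_hi = [
            i
            for i, r in p_assign.items()
            if r == r_hi
            and (production[i].agent.lemma if role == "agent" else production[i].patient.lemma)
            == lem
        ]
        rng.shuffle(cands_hi)
        done = False
        for i in cands_hi:
            verb = production[i].verb.lemma
            cands_lo = [
                j
                for j, r in p_assign.items()
                if r == r_lo
                and production[j].verb.lemma == verb
                and (
                    production[j].agent.lemma
                    if role == "agent"
                    else production[j].patient.lemma
                )
                != lem
            ]
            if cands_lo:
                j = cands_lo[rng.integers(len(cands_lo))]
                for idx, src, dst in ((i, r_hi, r_lo), (j, r_lo, r_hi)):
                    s = production[idx]
                    agent_ct[src][s.agent.lemma] -= 1
                    patient_ct[src][s.patient.lemma] -= 1
                    agent_ct[dst][s.agent.lemma] += 1
                    patient_ct[dst][s.patient.lemma] += 1
                    p_assign[idx] = dst
                done = True
                break
        if not done:
            break
    if worst() is not None:
        raise ScheduleError(
            "run scheduling could not balance noun-role counts within tolerance"
        )


# ---------------------------------------------------------------------------
# Summary / audit
# ---------------------------------------------------------------------------


def design_summary(obj: StimulusSet | Lexicon | list[SentenceSpec]) -> dict:
    """Counts and lexical statistics for a stimulus set or lexicon.

    Returns a dict with ``verb_counts``, ``agent_counts``, ``patient_counts``,
    ``pattern_counts`` (production + question trials only) and
    ``length_stats`` (mean and population SD of lemma character counts per
    lexical class present).
    """
    if isinstance(obj, Lexicon):
        stats = {}
        for cls_name, items in (
            ("sport", obj.nouns_of("sport")),
            ("music", obj.nouns_of("music")),
            ("contact", obj.verbs_of("contact")),
            ("perception", obj.verbs_of("perception")),
        ):
            if items:
                mean, sd = length_stats(items)
                stats[cls_name] = {"mean_length": mean, "sd_length": sd}
        if not stats:
            raise EmptySummaryError("empty lexicon")
        return {"length_stats": stats}

    sentences = list(obj.sentences) if isinstance(obj, StimulusSet) else list(obj)
    of_interest = [s for s in sentences if s.trial_type in ("production", "question")]
    if not sentences:
        raise EmptySummaryError("empty stimulus set")
    classes: dict[str, list[LexicalItem]] = {}
    for s in of_interest:
        for it in (s.agent, s.patient, s.verb):
            classes.setdefault(it.category, [])
    length_by_class = {}
    seen: dict[str, set[str]] = {c: set() for c in classes}
    items_by_class: dict[str, list[LexicalItem]] = {c: [] for c in classes}
    for s in of_interest:
        for it in (s.agent, s.patient, s.verb):
            if it.lemma not in seen[it.category]:
                seen[it.category].add(it.lemma)
                items_by_class[it.category].append(it)
    for c, items in items_by_class.items():
        mean, sd = length_stats(items)
        length_by_class[c] = {"mean_length": mean, "sd_length": sd}
    return {
        "verb_counts": Counter(s.verb.lemma for s in of_interest),
        "agent_counts": Counter(s.agent.lemma for s in of_interest),
        "patient_counts": Counter(s.patient.lemma for s in of_interest),
        "pattern_counts": Counter(s.category_pattern for s in of_interest),
        "voice_counts": Counter((s.voice, s.passive_order) for s in of_interest),
        "length_stats": length_by_class,
    }


def build_design(
    n_target: int = 288,
    n_questions: int = 36,
    n_fillers: int = 72,
    seed: int = 0,
    lexicon: Lexicon | None = None,
    n_runs: int = 6,
) -> StimulusSet:
    """End-to-end design construction: pool -> balanced set -> voice ->
    question split -> fillers -> run schedule."""
    from .lexicon import load_lexicon

    lex = lexicon or load_lexicon()
    rng = np.random.default_rng(seed)
    s_select, s_voice, s_split, s_fill, s_sched = rng.integers(2**31, size=5)
    pool = enumerate_pool(list(lex.nouns), list(lex.verbs))
    selected = select_balanced_set(pool, n_target=n_target, seed=int(s_select))
    voiced = assign_voice_and_order(selected, seed=int(s_voice))
    production, questions = split_questions(
        voiced, n_questions=n_questions, seed=int(s_split)
    )
    fillers = make_fillers(n=n_fillers, seed=int(s_fill))
    return schedule_runs(
        production, fillers, questions, seed=int(s_sched), n_runs=n_runs
    )
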