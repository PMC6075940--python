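"""Artificial past-tense language: phonemes, corpus, novel items, pattern encoding.

The learning domain is a 500-verb artificial language built from
consonant-vowel templates over an English-like phoneme set.  Each phoneme
is a distributed code over 19 binary articulatory features; each verb is a
tri-phonemic monosyllable with one of four past-tense formation classes:

* ``regular``      -- stem + one of three affix allomorphs (/d/, /t/,
  syllabic /-ed/), conditioned by the final phoneme of the stem;
* ``no_change``    -- past tense identical to the stem (hit-hit);
* ``vowel_change`` -- internal vowel alternation (hide-hid);
* ``arbitrary``    -- suppletive past unrelated to the stem (go-went).

Rule generalisation is probed with novel verbs that each share two of
three phoneme slots with a training regular.  Networks see each verb as a
557-unit input (3 x 19 phonological + 500 localist lexical-semantic) and
must produce a 62-unit output (3 x 19 past-tense phonology + 5 affix
units).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

N_FEATURES = 19
N_SLOTS = 3
N_LEXICAL = 500
N_AFFIX = 5
N_INPUT = N_SLOTS * N_FEATURES + N_LEXICAL    # 557
N_OUTPUT = N_SLOTS * N_FEATURES + N_AFFIX     # 62

#: names of the 19 binary articulatory features, in feature-vector order
FEATURE_NAMES = (
    "consonantal", "sonorant", "voiced", "nasal", "stop", "fricative",
    "affricate", "approximant", "lateral", "labial", "coronal", "dorsal",
    "palatal", "high", "low", "front", "back", "rounded", "tense_strident",
)
_F = {name: i for i, name in enumerate(FEATURE_NAMES)}

VERB_CLASSES = ("regular", "no_change", "vowel_change", "arbitrary")
AFFIXES = ("none", "t", "d", "syllabic_ed")

#: 5-unit output codes for the past-tense affix: unit 1 marks the presence
#: of an affix, unit 2 its voicing (/d/-type = 1), unit 3 syllabicity
#: (the /-ed/ allomorph); units 4-5 are reserved and fixed at 0.
AFFIX_CODES = {
    "none": (0, 0, 0, 0, 0),
    "t": (1, 0, 0, 0, 0),
    "d": (1, 1, 0, 0, 0),
    "syllabic_ed": (1, 1, 1, 0, 0),
}

DEFAULT_CLASS_COUNTS = (410, 20, 68, 2)
DEFAULT_N_NOVEL = 410


@dataclass(frozen=True)
class Phoneme:
    """One segment: a symbol plus its 19-bit articulatory feature tuple."""

    symbol: str
    features: tuple
    category: str        # "consonant" | "vowel"
    voiced: bool
    dental_stop: bool    # /t/,/d/-class segments conditioning syllabic /-ed/

    def __post_init__(self):
        if len(self.features) != N_FEATURES:
            raise ValueError(f"{self.symbol}: feature tuple must have length {N_FEATURES}")


def _feat(*names: str) -> tuple:
    bits = [0] * N_FEATURES
    for name in names:
        bits[_F[name]] = 1
    return tuple(bits)


# symbol -> feature names; an English-like inventory of 24 consonants and
# 10 vowels (ASCII symbols: N=/ng/, T=/th/, D=/dh/, S=/sh/, Z=/zh/,
# C=/ch/, J=/dzh/, I,E,U,V = lax vowels, a=/ae/, A=/ah/).
_CONSONANTS = {
    "p": ("consonantal", "stop", "labial"),
    "b": ("consonantal", "voiced", "stop", "labial"),
    "t": ("consonantal", "stop", "coronal"),
    "d": ("consonantal", "voiced", "stop", "coronal"),
    "k": ("consonantal", "stop", "dorsal"),
    "g": ("consonantal", "voiced", "stop", "dorsal"),
    "m": ("consonantal", "sonorant", "voiced", "nasal", "labial"),
    "n": ("consonantal", "sonorant", "voiced", "nasal", "coronal"),
    "N": ("consonantal", "sonorant", "voiced", "nasal", "dorsal"),
    "f": ("consonantal", "fricative", "labial"),
    "v": ("consonantal", "voiced", "fricative", "labial"),
    "T": ("consonantal", "fricative", "coronal"),
    "D": ("consonantal", "voiced", "fricative", "coronal"),
    "s": ("consonantal", "fricative", "coronal", "tense_strident"),
    "z": ("consonantal", "voiced", "fricative", "coronal", "tense_strident"),
    "S": ("consonantal", "fricative", "palatal", "tense_strident"),
    "Z": ("consonantal", "voiced", "fricative", "palatal", "tense_strident"),
    "C": ("consonantal", "affricate", "palatal", "tense_strident"),
    "J": ("consonantal", "voiced", "affricate", "palatal", "tense_strident"),
    "h": ("consonantal", "fricative", "dorsal"),
    "l": ("consonantal", "sonorant", "voiced", "approximant", "lateral", "coronal"),
    "r": ("consonantal", "sonorant", "voiced", "approximant", "coronal"),
    "w": ("consonantal", "sonorant", "voiced", "approximant", "labial", "back", "rounded"),
    "y": ("consonantal", "sonorant", "voiced", "approximant", "palatal", "high", "front"),
}
_VOWELS = {
    "i": ("sonorant", "voiced", "high", "front", "tense_strident"),
    "I": ("sonorant", "voiced", "high", "front"),
    "e": ("sonorant", "voiced", "front", "tense_strident"),
    "E": ("sonorant", "voiced", "front"),
    "a": ("sonorant", "voiced", "low", "front"),
    "A": ("sonorant", "voiced", "low", "back"),
    "u": ("sonorant", "voiced", "high", "back", "rounded", "tense_strident"),
    "U": ("sonorant", "voiced", "high", "back", "rounded"),
    "o": ("sonorant", "voiced", "back", "rounded", "tense_strident"),
    "V": ("sonorant", "voiced", "back"),
}


class PhonemeInventory:
    """Fixed phoneme set with feature-vector encode/decode helpers."""

    def __init__(self, phonemes: Sequence[Phoneme]):
        self.phonemes = tuple(phonemes)
        self.by_symbol = {p.symbol: p for p in self.phonemes}
        if len(self.by_symbol) != len(self.phonemes):
            raise ValueError("duplicate phoneme symbols")
        seen = {}
        for p in self.phonemes:
            if p.features in seen:
                raise ValueError(f"{p.symbol} and {seen[p.features]} share a feature tuple")
            seen[p.features] = p.symbol
        self.consonants = tuple(p for p in self.phonemes if p.category == "consonant")
        self.vowels = tuple(p for p in self.phonemes if p.category == "vowel")
        self._matrix = np.array([p.features for p in self.phonemes], dtype=np.int64)

    def __len__(self):
        return len(self.phonemes)

    def __getitem__(self, symbol: str) -> Phoneme:
        return self.by_symbol[symbol]

    def encode(self, symbol: str) -> np.ndarray:
        return np.array(self.by_symbol[symbol].features, dtype=np.float64)

    def decode(self, features) -> Phoneme:
        """Nearest phoneme by Hamming distance to a (possibly noisy) feature vector."""
        bits = (np.asarray(features, dtype=np.float64) >= 0.5).astype(np.int64)
        dist = np.abs(self._matrix - bits[None, :]).sum(axis=1)
        return self.phonemes[int(np.argmin(dist))]

    def same_category(self, symbol: str) -> tuple:
        pool = self.consonants if self.by_symbol[symbol].category == "consonant" else self.vowels
        return pool


def build_phoneme_inventory() -> PhonemeInventory:
    """The fixed 34-phoneme inventory (24 consonants, 10 vowels)."""
    phonemes = []
    for sym, names in _CONSONANTS.items():
        feats = _feat(*names)
        phonemes.append(Phoneme(
            symbol=sym, features=feats, category="consonant",
            voiced=bool(feats[_F["voiced"]]),
            dental_stop=bool(feats[_F["stop"]] and feats[_F["coronal"]]),
        ))
    for sym, names in _VOWELS.items():
        feats = _feat(*names)
        phonemes.append(Phoneme(
            symbol=sym, features=feats, category="vowel",
            voiced=True, dental_stop=False,
        ))
    return PhonemeInventory(phonemes)


def allomorph_for(final: Phoneme) -> str:
    """Regular-affix allomorph conditioned by the stem-final phoneme.

    /t/,/d/-class finals take the syllabic /-ed/; other voiced finals take
    /d/; unvoiced finals take /t/ (cf. chat-chatted, tame-tamed,
    wrap-wrapped).
    """
    if final.dental_stop:
        return "syllabic_ed"
    return "d" if final.voiced else "t"


@dataclass(frozen=True)
class Verb:
    lexical_index: int           # 1..500
    stem: tuple                  # 3 phoneme symbols
    verb_class: str
    past_stem: tuple             # 3 phoneme symbols
    affix: str

    def __post_init__(self):
        if self.verb_class not in VERB_CLASSES:
            raise ValueError(f"unknown verb class {self.verb_class!r}")
        if self.affix not in AFFIXES:
            raise ValueError(f"unknown affix {self.affix!r}")


@dataclass(frozen=True)
class NovelItem:
    stem: tuple
    matched_regular_index: int   # lexical index of the training regular it resembles
    correct_allomorph: str


@dataclass
class CorpusConfig:
    class_counts: tuple = DEFAULT_CLASS_COUNTS
    n_novel: int = DEFAULT_N_NOVEL
    templates: tuple = ("CVC",)   # 3-character C/V strings


@dataclass
class Corpus:
    verbs: list
    class_counts: tuple
    novel_items: list
    inventory: PhonemeInventory
    seed: int | None = None

    def stems(self) -> set:
        return {v.stem for v in self.verbs}

    def by_class(self, verb_class: str) -> list:
        return [v for v in self.verbs if v.verb_class == verb_class]

    # -- encodings ---------------------------------------------------------

    def encode_stem(self, stem: tuple) -> np.ndarray:
        return np.concatenate([self.inventory.encode(s) for s in stem])

    def encode_verb(self, verb: Verb) -> tuple:
        x = np.zeros(N_INPUT)
        x[: N_SLOTS * N_FEATURES] = self.encode_stem(verb.stem)
        x[N_SLOTS * N_FEATURES + verb.lexical_index - 1] = 1.0
        t = np.zeros(N_OUTPUT)
        t[: N_SLOTS * N_FEATURES] = self.encode_stem(verb.past_stem)
        t[N_SLOTS * N_FEATURES:] = AFFIX_CODES[verb.affix]
        return x, t

    def encode_novel(self, item: NovelItem) -> tuple:
        """Novel items have no localist lexical entry: the 500 lexical units stay 0.

        The target is the regularised past (stem phonology unchanged) with
        the rule-correct affix for the stem-final phoneme.
        """
        x = np.zeros(N_INPUT)
        x[: N_SLOTS * N_FEATURES] = self.encode_stem(item.stem)
        t = np.zeros(N_OUTPUT)
        t[: N_SLOTS * N_FEATURES] = self.encode_stem(item.stem)
        t[N_SLOTS * N_FEATURES:] = AFFIX_CODES[item.correct_allomorph]
        return x, t

    def pattern_arrays(self) -> dict:
        """Dense pattern matrices used for training and assessment.

        Returns training inputs/targets, per-verb class indices (position
        in ``VERB_CLASSES``), novel inputs and novel allomorph indices
        (position in ``AFFIXES``, i.e. 1=t, 2=d, 3=syllabic).
        """
        n = len(self.verbs)
        X = np.zeros((n, N_INPUT))
        T = np.zeros((n, N_OUTPUT))
        cls = np.zeros(n, dtype=np.int64)
        for i, v in enumerate(sorted(self.verbs, key=lambda v: v.lexical_index)):
            X[i], T[i] = self.encode_verb(v)
            cls[i] = VERB_CLASSES.index(v.verb_class)
        m = len(self.novel_items)
        Xn = np.zeros((m, N_INPUT))
        allo = np.zeros(m, dtype=np.int64)
        for j, item in enumerate(self.novel_items):
            Xn[j], _ = self.encode_novel(item)
            allo[j] = AFFIXES.index(item.correct_allomorph)
        return {"X_train": X, "T_train": T, "class_idx": cls,
                "X_novel": Xn, "novel_allomorph": allo}

    # -- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "class_counts": list(self.class_counts),
            "verbs": [{"lexical_index": v.lexical_index, "stem": list(v.stem),
                       "verb_class": v.verb_class, "past_stem": list(v.past_stem),
                       "affix": v.affix} for v in self.verbs],
            "novel_items": [{"stem": list(it.stem),
                             "matched_regular_index": it.matched_regular_index,
                             "correct_allomorph": it.correct_allomorph}
                            for it in self.novel_items],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Corpus":
        data = json.loads(text)
        verbs = [Verb(lexical_index=v["lexical_index"], stem=tuple(v["stem"]),
                      verb_class=v["verb_class"], past_stem=tuple(v["past_stem"]),
                      affix=v["affix"]) for v in data["verbs"]]
        novel = [NovelItem(stem=tuple(it["stem"]),
                           matched_regular_index=it["matched_regular_index"],
                           correct_allomorph=it["correct_allomorph"])
                 for it in data["novel_items"]]
        return cls(verbs=verbs, class_counts=tuple(data["class_counts"]),
                   novel_items=novel, inventory=build_phoneme_inventory(),
                   seed=data.get("seed"))

    def pattern_table(self):
        """Flat pattern dump: one row per item with id, class and all bits."""
        import pandas as pd

        rows = []
        for v in sorted(self.verbs, key=lambda v: v.lexical_index):
            x, t = self.encode_verb(v)
            rows.append((f"verb_{v.lexical_index}", v.verb_class,
                         "".join(str(int(b)) for b in x),
                         "".join(str(int(b)) for b in t)))
        for j, item in enumerate(self.novel_items):
            x, t = self.encode_novel(item)
            rows.append((f"novel_{j + 1}", "novel",
                         "".join(str(int(b)) for b in x),
                         "".join(str(int(b)) for b in t)))
        return pd.DataFrame(rows, columns=["id", "class", "input_bits", "target_bits"])


def _template_stems(inventory: PhonemeInventory, template: str):
    pools = [inventory.consonants if c == "C" else inventory.vowels for c in template]
    return [tuple(p.symbol for p in combo) for combo in product(*pools)]


def derive_past_form(stem: tuple, verb_class: str, rng: np.random.Generator,
                     inventory: PhonemeInventory, stem_pool: list | None = None):
    """Past stem and affix for one verb, per its formation class.

    ``stem_pool`` supplies candidate unrelated stems for the arbitrary
    class (suppletive pasts share no slot-wise phoneme with the stem).
    """
    if verb_class == "regular":
        return stem, allomorph_for(inventory[stem[-1]])
    if verb_class == "no_change":
        return stem, "none"
    if verb_class == "vowel_change":
        vowels = [p.symbol for p in inventory.vowels if p.symbol != stem[1]]
        new_vowel = vowels[rng.integers(len(vowels))]
        return (stem[0], new_vowel, stem[2]), "none"
    if verb_class == "arbitrary":
        if not stem_pool:
            raise ValueError("arbitrary class needs a pool of candidate past stems")
        for _ in range(1000):
            cand = stem_pool[rng.integers(len(stem_pool))]
            if all(a != b for a, b in zip(cand, stem)):
                return cand, "none"
        raise RuntimeError("could not find an unrelated past stem")
    raise ValueError(f"unknown verb class {verb_class!r}")


def generate_corpus(seed: int, config: CorpusConfig | None = None) -> Corpus:
    """Sample the training corpus and its novel generalisation set.

    Stems are drawn without replacement from the template space (CVC by
    default), shuffled, and assigned to the four verb classes in the
    configured proportions (410/20/68/2 by default).  Reproducible for a
    given seed.
    """
    config = config or CorpusConfig()
    inventory = build_phoneme_inventory()
    rng = np.random.default_rng(seed)

    stems = []
    for template in config.templates:
        stems.extend(_template_stems(inventory, template))
    stems = sorted(set(stems))
    n_verbs = sum(config.class_counts)
    if n_verbs + config.n_novel > len(stems):
        raise ValueError(
            f"template space ({len(stems)} stems) cannot supply "
            f"{n_verbs} training + {config.n_novel} novel stems")

    order = rng.permutation(len(stems))
    chosen = [stems[i] for i in order[:n_verbs]]
    spare = [stems[i] for i in order[n_verbs:]]  # pool for arbitrary pasts

    labels = [cls for cls, k in zip(VERB_CLASSES, config.class_counts) for _ in range(k)]
    verbs = []
    for idx, (stem, cls) in enumerate(zip(chosen, labels), start=1):
        past_stem, affix = derive_past_form(stem, cls, rng, inventory, stem_pool=spare)
        verbs.append(Verb(lexical_index=idx, stem=stem, verb_class=cls,
                          past_stem=past_stem, affix=affix))
    rng.shuffle(verbs)
    verbs = [Verb(lexical_index=i, stem=v.stem, verb_class=v.verb_class,
                  past_stem=v.past_stem, affix=v.affix)
             for i, v in enumerate(verbs, start=1)]

    corpus = Corpus(verbs=verbs, class_counts=tuple(config.class_counts),
                    novel_items=[], inventory=inventory, seed=seed)
    if config.n_novel:
        novel_seed = int(rng.integers(2**31))
        corpus.novel_items = generate_novel_set(corpus, novel_seed, n_novel=config.n_novel)
    return corpus


def generate_novel_set(corpus: Corpus, seed: int, n_novel: int = DEFAULT_N_NOVEL,
                       max_retries: int = 200) -> list:
    """Novel verbs for rule generalisation, one per sampled training regular.

    Each item copies two slots of its matched regular verbatim and
    replaces the third (chosen at random) with a different phoneme of the
    same category; the result must not collide with any training stem or
    earlier novel stem.  The rule-correct allomorph is recomputed from the
    (possibly new) final phoneme.
    """
    inventory = corpus.inventory
    rng = np.random.default_rng(seed)
    regulars = corpus.by_class("regular")
    if len(regulars) < n_novel:
        raise ValueError(f"corpus has {len(regulars)} regulars; need >= {n_novel}")
    matched = [regulars[i] for i in rng.permutation(len(regulars))[:n_novel]]

    train_stems = corpus.stems()
    used = set()
    items = []
    for reg in matched:
        for _ in range(max_retries):
            slot = int(rng.integers(N_SLOTS))
            pool = [p.symbol for p in inventory.same_category(reg.stem[slot])
                    if p.symbol != reg.stem[slot]]
            replacement = pool[rng.integers(len(pool))]
            stem = tuple(replacement if i == slot else s for i, s in enumerate(reg.stem))
            if stem not in train_stems and stem not in used:
                break
        else:
            raise RuntimeError("could not build a unique novel stem within retry budget")
        used.add(stem)
        items.append(NovelItem(stem=stem, matched_regular_index=reg.lexical_index,
                               correct_allomorph=allomorph_for(inventory[stem[-1]])))
    return items
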