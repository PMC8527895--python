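"""Toy language pairs and time-aligned synthetic transcripts.

The generator emulates the structure of an L1/L2 listening study: a
"native" and a "target" language share part of their phoneme inventory,
the target language additionally contains phonemes absent from the native
one (the "new" contrasts), and each language carries its own MaxEnt
phonotactic grammar.  Transcripts are non-overlapping phoneme intervals
grouped into words (2-6 phonemes) and sentences (5-12 words), with content
words flagged and assigned rows of a word-embedding table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phonotactics import PhonotacticGrammar, random_grammar

#: Phonetic articulatory feature names (19 binary dimensions per phoneme).
PHONETIC_FEATURES = [
    "voiced", "unvoiced", "sonorant", "syllabic", "consonantal",
    "approximant", "plosive", "strident", "labial", "coronal", "anterior",
    "dorsal", "nasal", "fricative", "obstruent", "front", "back", "high",
    "low",
]

_VOWEL_POOL = ["a", "e", "i", "o", "u", "y", "ae", "oe"]
_CONS_POOL = ["p", "t", "k", "b", "d", "g", "m", "n", "s", "z", "f", "v",
              "l", "r", "w", "j", "h", "sh", "ch", "th", "ng", "x"]


@dataclass
class Phone:
    symbol: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Word:
    text: str
    phone_span: tuple[int, int]  # [i0, i1) indices into transcript.phones
    content: bool
    start: float
    end: float


@dataclass
class StimulusTranscript:
    """Time-aligned phonemes, words and sentence boundaries."""

    phones: list[Phone]
    words: list[Word]
    sentence_spans: list[tuple[int, int]]  # [w0, w1) indices into words
    duration: float

    def word_phones(self, word: Word) -> list[Phone]:
        return self.phones[word.phone_span[0]:word.phone_span[1]]

    def word_symbols(self, word: Word) -> tuple[str, ...]:
        return tuple(p.symbol for p in self.word_phones(word))


@dataclass
class EmbeddingTable:
    """word -> D-dimensional feature vector."""

    vectors: dict[str, np.ndarray]
    dim: int

    def __post_init__(self) -> None:
        for w, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.dim,):
                raise ValueError(f"embedding for {w!r} has wrong dimension")
            self.vectors[w] = v

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[word]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({w: v for w, v in self.vectors.items()}).T

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EmbeddingTable":
        return cls({str(w): df.loc[w].to_numpy(float) for w in df.index},
                   dim=df.shape[1])


@dataclass
class LexiconEntry:
    text: str
    phones: tuple[str, ...]
    content: bool


@dataclass
class ToyLanguagePair:
    inventory_l1: list[str]
    inventory_l2: list[str]
    shared: list[str]
    unique_l2: list[str]
    grammar_l1: PhonotacticGrammar
    grammar_l2: PhonotacticGrammar
    feature_table: pd.DataFrame  # phoneme x 19 binary
    lexicon: list[LexiconEntry] = field(default_factory=list)
    embeddings: EmbeddingTable | None = None

    def __post_init__(self) -> None:
        if not set(self.shared) <= (set(self.inventory_l1) & set(self.inventory_l2)):
            raise ValueError("shared phonemes must occur in both inventories")
        if set(self.unique_l2) & set(self.inventory_l1):
            raise ValueError("unique_l2 phonemes must be absent from L1")
        rows = [tuple(self.feature_table.loc[p]) for p in self.feature_table.index]
        if len(set(rows)) != len(rows):
            raise ValueError("phonetic feature rows must be distinct")

    def is_vowel(self, symbol: str) -> bool:
        return bool(self.feature_table.loc[symbol, "syllabic"])


def _vowel_row(rng: np.random.Generator) -> np.ndarray:
    row = np.zeros(len(PHONETIC_FEATURES), dtype=int)
    f = {n: i for i, n in enumerate(PHONETIC_FEATURES)}
    row[f["voiced"]] = 1
    row[f["sonorant"]] = 1
    row[f["syllabic"]] = 1
    row[f["approximant"]] = 1
    front = rng.integers(0, 2)
    row[f["front"]] = front
    row[f["back"]] = 1 - front
    high = rng.integers(0, 2)
    row[f["high"]] = high
    row[f["low"]] = 1 - high
    return row


def _consonant_row(rng: np.random.Generator) -> np.ndarray:
    row = np.zeros(len(PHONETIC_FEATURES), dtype=int)
    f = {n: i for i, n in enumerate(PHONETIC_FEATURES)}
    row[f["consonantal"]] = 1
    voiced = int(rng.integers(0, 2))
    row[f["voiced"]] = voiced
    row[f["unvoiced"]] = 1 - voiced
    manner = rng.choice(["plosive", "fricative", "nasal", "approximant"])
    row[f[manner]] = 1
    if manner in ("nasal", "approximant"):
        row[f["sonorant"]] = 1
        row[f["voiced"]] = 1
        row[f["unvoiced"]] = 0
    else:
        row[f["obstruent"]] = 1
        if manner == "fricative":
            row[f["strident"]] = int(rng.integers(0, 2))
    place = np.zeros(3, dtype=int)
    while not place.any():
        place = (rng.random(3) < 0.45).astype(int)
    for bit, name in zip(place, ("labial", "coronal", "dorsal")):
        row[f[name]] = int(bit)
    if row[f["coronal"]]:
        row[f["anterior"]] = int(rng.integers(0, 2))
    # secondary articulation (palatalisation/velarisation) bits
    row[f["front"]] = int(rng.random() < 0.25)
    row[f["high"]] = int(rng.random() < 0.25)
    return row


def _feature_table(vowels: list[str], consonants: list[str],
                   rng: np.random.Generator, max_tries: int = 200) -> pd.DataFrame:
    """Distinct, linearly independent feature rows for every phoneme."""
    symbols = vowels + consonants
    for _ in range(max_tries):
        rows = [_vowel_row(rng) for _ in vowels] + \
               [_consonant_row(rng) for _ in consonants]
        mat = np.array(rows)
        distinct = len({tuple(r) for r in rows}) == len(rows)
        if distinct and np.linalg.matrix_rank(mat.astype(float)) == len(rows):
            return pd.DataFrame(mat, index=symbols, columns=PHONETIC_FEATURES)
    raise ValueError(
        "could not draw as many distinct independent 19-bit feature rows as "
        "phonemes; reduce the inventory size")


def make_toy_languages(n_shared: int = 6, n_unique: int = 3,
                       m_constraints: int = 4, seed: int = 0,
                       n_lexicon: int = 120, embedding_dim: int = 16
                       ) -> ToyLanguagePair:
    """Build a toy native/target language pair.

    The target (L2) inventory is ``n_shared`` phonemes shared with L1 plus
    ``n_unique`` phonemes absent from L1; L1 additionally holds its own
    unique phonemes.  Both languages get random bigram MaxEnt grammars
    with differing constraint weights.
    """
    if n_shared < 1:
        raise ValueError("phoneme overlap between the languages is required")
    if n_shared + n_unique < 4:
        raise ValueError("need at least 4 phonemes in the target language")
    if m_constraints < 1:
        raise ValueError("m_constraints must be >= 1")
    rng = np.random.default_rng(seed)

    n_vow = max(1, round(n_shared / 3))
    shared = _VOWEL_POOL[:n_vow] + _CONS_POOL[:n_shared - n_vow]
    cons_rest = _CONS_POOL[n_shared - n_vow:]
    if n_unique * 2 > len(cons_rest):
        raise ValueError("phoneme pools exhausted; reduce inventory sizes")
    unique_l2 = cons_rest[:n_unique]
    unique_l1 = cons_rest[n_unique:2 * n_unique]

    vowels = [s for s in shared if s in _VOWEL_POOL]
    consonants = [s for s in shared if s not in _VOWEL_POOL] + unique_l2 + unique_l1
    table = _feature_table(vowels, consonants, rng)

    inventory_l1 = shared + unique_l1
    inventory_l2 = shared + unique_l2
    grammar_l1 = random_grammar(inventory_l1, m_constraints, rng)
    grammar_l2 = random_grammar(inventory_l2, m_constraints, rng)

    lexicon = _make_lexicon(inventory_l2, vowels, n_lexicon, rng)
    content_words = [e.text for e in lexicon if e.content]
    emb = EmbeddingTable(
        {w: rng.standard_normal(embedding_dim) for w in content_words},
        dim=embedding_dim)
    return ToyLanguagePair(inventory_l1, inventory_l2, shared, unique_l2,
                           grammar_l1, grammar_l2, table, lexicon, emb)


def _make_lexicon(inventory: list[str], vowels: list[str], n_types: int,
                  rng: np.random.Generator) -> list[LexiconEntry]:
    """Word types over the target inventory; ~60% are content words."""
    entries: dict[str, LexiconEntry] = {}
    n_content = round(0.6 * n_types)
    tries = 0
    while len(entries) < n_types and tries < 50 * n_types:
        tries += 1
        content = len([e for e in entries.values() if e.content]) < n_content
        length = int(rng.integers(3, 7)) if content else int(rng.integers(2, 4))
        phones = tuple(rng.choice(inventory, size=length))
        text = "".join(phones)
        if text not in entries:
            entries[text] = LexiconEntry(text, phones, content)
    return list(entries.values())


def sample_transcript(lang: ToyLanguagePair, duration_s: float, seed: int = 0,
                      mean_phone_s: float = 0.08) -> StimulusTranscript:
    """Sample a transcript tiling ``duration_s`` with phoneme intervals.

    Words abut within a sentence; short pauses separate sentences.
    Phoneme durations are gamma-distributed with the stated mean.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    func_types = [e for e in lang.lexicon if not e.content]
    cont_types = [e for e in lang.lexicon if e.content]
    # function-word types are individually more frequent, which keeps the
    # token-level content fraction near 40%
    types = func_types + cont_types
    weights = np.array([2.5] * len(func_types) + [1.0] * len(cont_types))
    weights /= weights.sum()

    phones: list[Phone] = []
    words: list[Word] = []
    sentence_spans: list[tuple[int, int]] = []
    t = 0.0
    shape = 4.0
    scale = mean_phone_s / shape
    done = False
    while not done:
        w0 = len(words)
        n_words = int(rng.integers(5, 13))
        for _ in range(n_words):
            entry = types[int(rng.choice(len(types), p=weights))]
            i0 = len(phones)
            for sym in entry.phones:
                d = max(0.03, float(rng.gamma(shape, scale)))
                if t + d > duration_s:
                    done = True
                    break
                phones.append(Phone(sym, t, t + d))
                t += d
            if len(phones) > i0:
                words.append(Word(entry.text, (i0, len(phones)), entry.content,
                                  phones[i0].start, phones[-1].end))
            if done:
                break
        if len(words) > w0:
            sentence_spans.append((w0, len(words)))
        t += float(rng.uniform(0.15, 0.35))  # inter-sentence pause
        if t >= duration_s:
            done = True
    return StimulusTranscript(phones, words, sentence_spans, duration_s)
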