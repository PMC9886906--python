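"""Artificial-lexicon generation and slot-based encoding.

This module builds small artificial languages whose statistical structure
mirrors the psycholinguistic covariates of a monosyllabic English corpus:
Zipfian word frequencies, rime-consistency families with a controlled
proportion of exception words, orthographic neighbourhoods, homophony with
context tags, and a semantic-richness (imageability) proxy given by the
number of active semantic features.

Words are monosyllabic ``onset + rime`` strings over a small alphabet with
designated vowel letters.  Each letter has a canonical phoneme; exception
words pronounce their rime's vowel with an alternate phoneme, so that words
sharing a rime spelling may disagree on its pronunciation (the basis of the
rime-consistency measure).

Representations follow the slot scheme of triangle-model simulations:

* orthography — 14 letter slots x ``alphabet_size`` units, the first vowel
  aligned on slot 5 (slot 6 for a second vowel), consonants adjacent;
* phonology — 8 phoneme slots x 25 binary phonological features
  (slots 1-3 onset, slot 4 vowel, slots 5-8 coda);
* semantics — a sparse binary feature vector; the number of active features
  doubles as the imageability proxy;
* context — 4 units disambiguating homophone meanings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

N_ORTH_SLOTS = 14
N_PHON_SLOTS = 8
N_PHON_FEATURES = 25
N_CONTEXT_UNITS = 4
NULL_PHONEME = "_"

VOWEL_POOL = "aeiou"
CONSONANT_POOL = "bcdfghjklmnpqrstvwxyz"


class LanguageError(ValueError):
    """Raised for infeasible language specifications or encoding overflows."""


@dataclass(frozen=True)
class LanguageSpec:
    """Parameters of an artificial language.

    Defaults define the desk-scale study language: 300 monosyllabic words
    over a 12-letter alphabet (3 vowels), 25 onsets x 30 rimes, 20%
    exception words, Zipf exponent 1, 60 semantic features with 2-8 active
    per word, and 3 homophone pairs.
    """

    n_words: int = 300
    alphabet_size: int = 12
    n_vowels: int = 3
    n_onsets: int = 25
    n_rimes: int = 30
    max_onset_len: int = 2
    max_coda_len: int = 2
    exception_fraction: float = 0.2
    zipf_exponent: float = 1.0
    n_sem_features: int = 60
    sem_features_min: int = 2
    sem_features_max: int = 8
    n_homophone_pairs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.exception_fraction < 1.0):
            raise LanguageError("exception_fraction must be in [0, 1)")
        for name in ("n_words", "alphabet_size", "n_vowels", "n_onsets",
                     "n_rimes", "n_sem_features", "sem_features_min",
                     "sem_features_max"):
            if getattr(self, name) <= 0:
                raise LanguageError(f"{name} must be positive")
        if self.alphabet_size > 26:
            raise LanguageError("alphabet_size must be <= 26")
        if self.n_vowels >= self.alphabet_size:
            raise LanguageError("need at least one consonant letter")
        if self.n_vowels > len(VOWEL_POOL):
            raise LanguageError(f"at most {len(VOWEL_POOL)} vowel letters")
        if self.sem_features_max < self.sem_features_min:
            raise LanguageError("sem_features_max < sem_features_min")
        if self.n_sem_features < 2 * self.sem_features_max:
            # homophone meanings need disjoint feature sets
            raise LanguageError("n_sem_features too small for disjoint "
                                "homophone semantics")
        if self.n_homophone_pairs < 0:
            raise LanguageError("n_homophone_pairs must be >= 0")
        if 2 * self.n_homophone_pairs >= self.n_words:
            raise LanguageError("too many homophone pairs for n_words")

    @property
    def vowels(self) -> str:
        return VOWEL_POOL[: self.n_vowels]

    @property
    def consonants(self) -> str:
        return CONSONANT_POOL[: self.alphabet_size - self.n_vowels]

    @property
    def alphabet(self) -> str:
        return self.vowels + self.consonants

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LanguageSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class LexicalItem:
    """One word: spelling, pronunciation, meaning and covariates.

    ``context_index`` is 0 for non-homophones and 1-4 for the meaning tag
    of a homophone; ``img`` (imageability proxy) always equals
    ``len(sem_features)``.
    """

    letters: str
    phonemes: tuple[str, ...]
    sem_features: frozenset[int]
    wf: float = 0.0
    ons: int = 0
    rc: float = 1.0
    img: int = 0
    context_index: int = 0


@dataclass(frozen=True)
class Nonword:
    letters: str
    acceptable_pronunciations: tuple[tuple[str, ...], ...]
    condition: str  # "consistent" | "inconsistent"


@dataclass
class Lexicon:
    """A generated language: items, phoneme inventory, alphabet classes."""

    items: list[LexicalItem]
    phoneme_inventory: dict[str, np.ndarray]
    alphabet: str
    vowels: str
    n_sem_features: int
    spec: LanguageSpec | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def vowel_phonemes(self) -> set[str]:
        """Phoneme labels filling the vowel slot (canonical + alternates)."""
        return {v for v in self.vowels} | {v.upper() for v in self.vowels}

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([it.wf for it in self.items])

    def top_k_indices(self, k: int) -> np.ndarray:
        """Indices of the k most frequent items (stable order)."""
        wf = self.frequencies
        order = np.argsort(-wf, kind="stable")
        return order[:k]

    # ------------------------------------------------------------------ io
    def to_tsv(self, items_path, inventory_path) -> None:
        with open(items_path, "w") as fh:
            fh.write(f"# alphabet={self.alphabet}\tvowels={self.vowels}"
                     f"\tn_sem_features={self.n_sem_features}\n")
            fh.write("letters\tphonemes\tsem_features\twf\tons\trc\timg"
                     "\tcontext_index\n")
            for it in self.items:
                feats = ",".join(str(i) for i in sorted(it.sem_features))
                fh.write(f"{it.letters}\t{' '.join(it.phonemes)}\t{feats}"
                         f"\t{it.wf!r}\t{it.ons}\t{it.rc!r}\t{it.img}"
                         f"\t{it.context_index}\n")
        with open(inventory_path, "w") as fh:
            fh.write("phoneme\tfeatures\n")
            for label, vec in self.phoneme_inventory.items():
                bits = "".join(str(int(b)) for b in vec)
                fh.write(f"{label}\t{bits}\n")

    @classmethod
    def from_tsv(cls, items_path, inventory_path) -> "Lexicon":
        with open(items_path) as fh:
            header = fh.readline().strip()
            meta = dict(kv.split("=", 1) for kv in
                        header.lstrip("# ").split("\t"))
            fh.readline()  # column header
            items = []
            for line in fh:
                (letters, phon, feats, wf, ons, rc, img, ctx) = \
                    line.rstrip("\n").split("\t")
                items.append(LexicalItem(
                    letters=letters,
                    phonemes=tuple(phon.split()),
                    sem_features=frozenset(int(i) for i in feats.split(",")),
                    wf=float(wf), ons=int(ons), rc=float(rc), img=int(img),
                    context_index=int(ctx)))
        inventory = {}
        with open(inventory_path) as fh:
            fh.readline()
            for line in fh:
                label, bits = line.rstrip("\n").split("\t")
                inventory[label] = np.array([int(b) for b in bits],
                                            dtype=float)
        return cls(items=items, phoneme_inventory=inventory,
                   alphabet=meta["alphabet"], vowels=meta["vowels"],
                   n_sem_features=int(meta["n_sem_features"]))


# --------------------------------------------------------------------------
# construction helpers
# --------------------------------------------------------------------------

def _split_rime(letters: str, vowels: str) -> tuple[str, str]:
    """Split a spelling into (onset, rime); rime starts at the first vowel."""
    for i, ch in enumerate(letters):
        if ch in vowels:
            return letters[:i], letters[i:]
    raise LanguageError(f"word {letters!r} has no vowel letter")


def _rime_phonemes(item: LexicalItem, vowel_phonemes: set[str]) -> tuple[str, ...]:
    for i, ph in enumerate(item.phonemes):
        if ph in vowel_phonemes:
            return item.phonemes[i:]
    raise LanguageError(f"word {item.letters!r} has no vowel phoneme")


def _make_inventory(spec: LanguageSpec, rng: np.random.Generator,
                    n_active: int = 9, min_hamming: int = 6) -> dict[str, np.ndarray]:
    """Random distinct binary feature vectors for every phoneme label.

    Labels: one phoneme per letter (same symbol) plus one alternate vowel
    phoneme per vowel letter (uppercase symbol) used by exception rimes,
    plus an all-zero null phoneme for empty slots.
    """
    labels = list(spec.alphabet) + [v.upper() for v in spec.vowels]
    inventory: dict[str, np.ndarray] = {NULL_PHONEME: np.zeros(N_PHON_FEATURES)}
    chosen: list[np.ndarray] = []
    for label in labels:
        for _ in range(20000):
            vec = np.zeros(N_PHON_FEATURES)
            vec[rng.choice(N_PHON_FEATURES, size=n_active, replace=False)] = 1.0
            if all(int(np.abs(vec - c).sum()) >= min_hamming for c in chosen):
                break
        else:  # pragma: no cover - generous attempt budget
            raise LanguageError("could not build a separable phoneme inventory")
        chosen.append(vec)
        inventory[label] = vec
    return inventory


def _assign_exceptions(spellings: list[str], vowels: str, target: int,
                       rng: np.random.Generator) -> set[str]:
    """Pick exception spellings, keeping exceptions a strict minority in
    every rime family, aiming at ``target`` exception words in total."""
    families: dict[str, list[str]] = {}
    for w in spellings:
        _, rime = _split_rime(w, vowels)
        families.setdefault(rime, []).append(w)
    caps = {rime: max((len(ws) - 1) // 2, 0) for rime, ws in families.items()}
    exceptions: set[str] = set()
    # fill families one at a time (exceptions cluster in particular rimes,
    # leaving other families fully consistent for the nonword test sets)
    rime_order = list(rng.permutation(sorted(families)))
    for rime in rime_order:
        if len(exceptions) >= target:
            break
        members = families[rime]
        picks = rng.permutation(len(members))[
            : min(caps[rime], target - len(exceptions))]
        exceptions |= {members[i] for i in picks}
    return exceptions


def build_language(spec: LanguageSpec) -> Lexicon:
    """Generate a lexicon from a language specification.

    Deterministic for a fixed ``spec.seed``.  Raises :class:`LanguageError`
    when the spec is infeasible (more words than onset x rime combinations,
    or too few onsets/rimes available).
    """
    rng = np.random.default_rng(spec.seed)
    vowels, consonants = spec.vowels, spec.consonants

    # onsets: consonant strings of length 1..max_onset_len
    onset_pool = [c for c in consonants]
    if spec.max_onset_len >= 2:
        onset_pool += ["".join(p) for p in
                       itertools.product(consonants, repeat=2)]
    if len(onset_pool) < spec.n_onsets:
        raise LanguageError("not enough distinct onsets available")
    onsets = [onset_pool[i] for i in
              rng.choice(len(onset_pool), size=spec.n_onsets, replace=False)]

    # rimes: vowel + coda of length 0..max_coda_len
    coda_pool = [""]
    for length in range(1, spec.max_coda_len + 1):
        coda_pool += ["".join(p) for p in
                      itertools.product(consonants, repeat=length)]
    rime_pool = [v + c for v in vowels for c in coda_pool]
    if len(rime_pool) < spec.n_rimes:
        raise LanguageError("not enough distinct rimes available")
    rimes = [rime_pool[i] for i in
             rng.choice(len(rime_pool), size=spec.n_rimes, replace=False)]

    n_base = spec.n_words - spec.n_homophone_pairs
    n_combos = spec.n_onsets * spec.n_rimes
    if n_base > n_combos:
        raise LanguageError(
            f"{spec.n_words} words requested but only {n_combos} "
            "onset x rime combinations exist")
    combo_idx = rng.choice(n_combos, size=n_base, replace=False)
    spellings = [onsets[i // spec.n_rimes] + rimes[i % spec.n_rimes]
                 for i in combo_idx]

    target_exc = int(round(spec.exception_fraction * spec.n_words))
    exceptions = _assign_exceptions(spellings, vowels, target_exc, rng)

    inventory = _make_inventory(spec, rng)

    def pronounce(word: str) -> tuple[str, ...]:
        onset, rime = _split_rime(word, vowels)
        vowel, coda = rime[0], rime[1:]
        vph = vowel.upper() if word in exceptions else vowel
        return tuple(onset) + (vph,) + tuple(coda)

    # homophone pairs duplicate a regular word's form with a second meaning
    regular = [w for w in spellings if w not in exceptions]
    sources = [regular[i] for i in
               rng.choice(len(regular), size=spec.n_homophone_pairs,
                          replace=False)] if spec.n_homophone_pairs else []

    records: list[dict] = [{"letters": w, "phonemes": pronounce(w),
                            "context_index": 0} for w in spellings]
    for w in sources:
        ctx = rng.choice(N_CONTEXT_UNITS, size=2, replace=False) + 1
        for rec in records:
            if rec["letters"] == w:
                rec["context_index"] = int(ctx[0])
        records.append({"letters": w, "phonemes": pronounce(w),
                        "context_index": int(ctx[1])})

    # semantics + imageability proxy; homophone meanings get disjoint sets
    used_by_form: dict[str, set[int]] = {}
    for rec in records:
        img = int(rng.integers(spec.sem_features_min,
                               spec.sem_features_max + 1))
        taken = used_by_form.get(rec["letters"], set())
        avail = np.array([f for f in range(spec.n_sem_features)
                          if f not in taken])
        feats = frozenset(int(f) for f in
                          rng.choice(avail, size=img, replace=False))
        used_by_form[rec["letters"]] = taken | set(feats)
        rec["sem_features"] = feats
        rec["img"] = img

    # Zipfian frequencies over a random rank order, normalized to sum 1
    ranks = rng.permutation(len(records)) + 1
    wf = ranks.astype(float) ** (-spec.zipf_exponent)
    wf /= wf.sum()
    for rec, f in zip(records, wf):
        rec["wf"] = float(f)

    items = [LexicalItem(**rec) for rec in records]
    lex = Lexicon(items=items, phoneme_inventory=inventory,
                  alphabet=spec.alphabet, vowels=vowels,
                  n_sem_features=spec.n_sem_features, spec=spec)
    # covariates computed from the finished lexicon
    lex.items = [replace(it,
                         rc=rime_consistency(lex, it),
                         ons=orth_neighbourhood(lex, it))
                 for it in items]
    return lex


# --------------------------------------------------------------------------
# covariates
# --------------------------------------------------------------------------

def rime_consistency(lexicon: Lexicon, item: LexicalItem) -> float:
    """Type-based rime consistency: friends / (friends + enemies).

    Friends are words (including the item) sharing both the item's rime
    spelling and its rime pronunciation; the denominator is all words
    sharing the rime spelling.
    """
    _, rime = _split_rime(item.letters, lexicon.vowels)
    vph = lexicon.vowel_phonemes
    my_pron = _rime_phonemes(item, vph)
    family = friends = 0
    for other in lexicon.items:
        _, other_rime = _split_rime(other.letters, lexicon.vowels)
        if other_rime != rime:
            continue
        family += 1
        if _rime_phonemes(other, vph) == my_pron:
            friends += 1
    return friends / family


def orth_neighbourhood(lexicon: Lexicon, item: LexicalItem) -> int:
    """Coltheart's N: other same-length words differing by exactly one letter."""
    n = 0
    for other in lexicon.items:
        if other is item or len(other.letters) != len(item.letters):
            continue
        diff = sum(a != b for a, b in zip(item.letters, other.letters))
        if diff == 1:
            n += 1
    return n


def log_frequency(wf: float | np.ndarray) -> float | np.ndarray:
    """Corpus-style log frequency: ln(relative frequency x 1e6 + 1)."""
    return np.log(np.asarray(wf) * 1e6 + 1.0)


# --------------------------------------------------------------------------
# encoders
# --------------------------------------------------------------------------

def encode_orthography(letters: str, alphabet: str, vowels: str,
                       n_slots: int = N_ORTH_SLOTS) -> np.ndarray:
    """Slot-coded orthography: one unit per (slot, letter).

    The first vowel is aligned on slot 5, a second (immediately following)
    vowel on slot 6; consonants occupy adjacent slots.  Raises
    :class:`LanguageError` when the word overflows the template
    (more than 4 pre-vowel consonants, or coda past the last slot).
    """
    letter_index = {ch: i for i, ch in enumerate(alphabet)}
    for ch in letters:
        if ch not in letter_index:
            raise LanguageError(f"letter {ch!r} of {letters!r} not in alphabet")
    onset, rime = _split_rime(letters, vowels)
    if len(onset) > 4:
        raise LanguageError(f"word {letters!r}: more than 4 pre-vowel "
                            "consonants do not fit slots 1-4")
    second_vowel = len(rime) > 1 and rime[1] in vowels
    coda = rime[2:] if second_vowel else rime[1:]
    if any(ch in vowels for ch in coda):
        raise LanguageError(f"word {letters!r}: more than two vowels")
    coda_start = 6 if second_vowel else 5  # 0-based slot index
    if coda_start + len(coda) > n_slots:
        raise LanguageError(f"word {letters!r}: coda overflows slot template")

    A = len(alphabet)
    vec = np.zeros(n_slots * A)

    def put(slot: int, ch: str) -> None:
        vec[slot * A + letter_index[ch]] = 1.0

    for i, ch in enumerate(onset):            # right-aligned, ends at slot 4
        put(4 - len(onset) + i, ch)
    put(4, rime[0])                           # first vowel on slot 5
    if second_vowel:
        put(5, rime[1])
    for i, ch in enumerate(coda):
        put(coda_start + i, ch)
    return vec


def phoneme_slots(phonemes: tuple[str, ...],
                  vowel_phonemes: set[str]) -> tuple[str, ...]:
    """Assign phonemes to the 8-slot template; empty slots get the null label.

    Onset consonants are right-aligned ending at slot 3, the vowel sits in
    slot 4, coda consonants fill slots 5-8 left-aligned.
    """
    vpos = [i for i, ph in enumerate(phonemes) if ph in vowel_phonemes]
    if len(vpos) != 1:
        raise LanguageError(f"syllable {phonemes!r} must have exactly one vowel")
    onset, coda = phonemes[: vpos[0]], phonemes[vpos[0] + 1:]
    if len(onset) > 3:
        raise LanguageError(f"syllable {phonemes!r}: more than 3 onset consonants")
    if len(coda) > 4:
        raise LanguageError(f"syllable {phonemes!r}: more than 4 coda consonants")
    slots = [NULL_PHONEME] * N_PHON_SLOTS
    for i, ph in enumerate(onset):
        slots[3 - len(onset) + i] = ph
    slots[3] = phonemes[vpos[0]]
    for i, ph in enumerate(coda):
        slots[4 + i] = ph
    return tuple(slots)


def encode_phonology(phonemes: tuple[str, ...],
                     inventory: dict[str, np.ndarray],
                     vowel_phonemes: set[str]) -> np.ndarray:
    """Slot-coded phonology: 8 slots x 25 phonological features."""
    slots = phoneme_slots(phonemes, vowel_phonemes)
    rows = []
    for ph in slots:
        if ph not in inventory:
            raise LanguageError(f"phoneme {ph!r} not in inventory")
        rows.append(inventory[ph])
    return np.concatenate(rows)


def encode_semantics(sem_features: frozenset[int] | set[int],
                     n_sem_features: int) -> np.ndarray:
    """Sparse binary semantic vector; every word must have >= 1 feature."""
    if not sem_features:
        raise LanguageError("word must have at least one semantic feature")
    idx = np.fromiter(sem_features, dtype=int)
    if idx.max() >= n_sem_features or idx.min() < 0:
        raise LanguageError("semantic feature index out of range")
    vec = np.zeros(n_sem_features)
    vec[idx] = 1.0
    return vec


def encode_context(context_index: int) -> np.ndarray:
    vec = np.zeros(N_CONTEXT_UNITS)
    if context_index:
        vec[context_index - 1] = 1.0
    return vec


@dataclass
class EncodedLexicon:
    """All items of a lexicon encoded once into dense pattern matrices."""

    lexicon: Lexicon
    orth: np.ndarray      # (n, 14 * alphabet_size)
    phon: np.ndarray      # (n, 200)
    sem: np.ndarray       # (n, n_sem_features)
    ctx: np.ndarray       # (n, 4)
    phon_slots: list[tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.lexicon)


def encode_lexicon(lexicon: Lexicon) -> EncodedLexicon:
    vph = lexicon.vowel_phonemes
    orth = np.stack([encode_orthography(it.letters, lexicon.alphabet,
                                        lexicon.vowels)
                     for it in lexicon.items])
    phon = np.stack([encode_phonology(it.phonemes, lexicon.phoneme_inventory,
                                      vph)
                     for it in lexicon.items])
    sem = np.stack([encode_semantics(it.sem_features, lexicon.n_sem_features)
                    for it in lexicon.items])
    ctx = np.stack([encode_context(it.context_index) for it in lexicon.items])
    slots = [phoneme_slots(it.phonemes, vph) for it in lexicon.items]
    return EncodedLexicon(lexicon=lexicon, orth=orth, phon=phon, sem=sem,
                          ctx=ctx, phon_slots=slots)


# --------------------------------------------------------------------------
# nonwords and sampling
# --------------------------------------------------------------------------

def generate_nonwords(lexicon: Lexicon, n: int, condition: str,
                      seed: int | np.random.Generator = 0) -> list[Nonword]:
    """Novel onset x rime combinations with attested rime pronunciations.

    ``consistent`` nonwords use rimes from fully consistent families (one
    acceptable pronunciation); ``inconsistent`` nonwords use rimes whose
    family attests several pronunciations (all are acceptable).
    """
    if condition not in ("consistent", "inconsistent"):
        raise LanguageError(f"unknown nonword condition {condition!r}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    vph = lexicon.vowel_phonemes

    onset_pron: dict[str, tuple[str, ...]] = {}
    rime_prons: dict[str, set[tuple[str, ...]]] = {}
    spellings = set()
    for it in lexicon.items:
        onset, rime = _split_rime(it.letters, lexicon.vowels)
        vpos = len(onset)
        onset_pron[onset] = it.phonemes[:vpos]
        rime_prons.setdefault(rime, set()).add(_rime_phonemes(it, vph))
        spellings.add(it.letters)

    want_multiple = condition == "inconsistent"
    rime_ok = [r for r, prons in rime_prons.items()
               if (len(prons) > 1) == want_multiple]

    # candidate onsets: prefer consonant strings never attested as onsets
    # (novel letter strings, as in behavioural nonword sets); consonant
    # letters are pronounced canonically, so the pronunciation is defined.
    consonants = sorted({ch for it in lexicon.items for ch in it.letters
                         if ch not in lexicon.vowels})
    novel = [c for c in consonants if c not in onset_pron]
    novel += [a + b for a in consonants for b in consonants
              if a + b not in onset_pron]
    onset_candidates = novel + sorted(onset_pron)

    candidates = []
    for onset in onset_candidates:
        for rime in sorted(rime_ok):
            w = onset + rime
            if w not in spellings:
                candidates.append((onset, rime))
    if len(candidates) < n:
        raise LanguageError(
            f"only {len(candidates)} unused {condition} combinations; "
            f"{n} requested")
    picks = rng.choice(len(candidates), size=n, replace=False)
    nonwords = []
    for i in picks:
        onset, rime = candidates[i]
        onset_ph = onset_pron.get(onset, tuple(onset))
        prons = tuple(sorted(onset_ph + rp for rp in rime_prons[rime]))
        nonwords.append(Nonword(letters=onset + rime,
                                acceptable_pronunciations=prons,
                                condition=condition))
    return nonwords


def sample_word(lexicon: Lexicon, rng: np.random.Generator,
                top_k: int | None = None) -> LexicalItem:
    """Frequency-weighted draw with replacement (optionally from the top-k)."""
    return lexicon.items[sample_indices(lexicon, rng, 1, top_k)[0]]


def sample_indices(lexicon: Lexicon, rng: np.random.Generator, size: int,
                   top_k: int | None = None) -> np.ndarray:
    """Vectorized frequency-weighted item-index draws."""
    wf = lexicon.frequencies
    if top_k is not None:
        idx = lexicon.top_k_indices(top_k)
        p = wf[idx] / wf[idx].sum()
        return idx[rng.choice(len(idx), size=size, p=p)]
    return rng.choice(len(wf), size=size, p=wf / wf.sum())
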