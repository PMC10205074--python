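"""Synthetic lexicons and frequency-tagged stimulus sequences.

The experimental paradigm presents isochronous syllables at 4 Hz grouped
into disyllabic units (words or pseudo-words) at 2 Hz.  Three lexicon
profiles are supported:

``native_like``
    words the listener can segment lexically; built so that the second
    syllable is predictable from the first (high within-word transitional
    probability).
``foreign_like``
    words carrying the same statistical (transition-probability) structure
    but treated as unknown wordforms.
``random``
    pseudo-words whose two syllable positions are filled by quasi-random,
    position-balanced draws, so the syllable stream carries no grouping cue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Syllable",
    "SyllableToken",
    "WordEntry",
    "Lexicon",
    "StimulusSequence",
    "build_lexicon",
    "generate_sequence",
    "generate_experiment",
]

# phoneme inventory with manner-of-articulation classes for the onset
_CONSONANTS: dict[str, str] = {
    "p": "plosive", "t": "plosive", "k": "plosive",
    "b": "plosive", "d": "plosive", "g": "plosive",
    "f": "fricative", "s": "fricative", "z": "fricative",
    "x": "fricative", "v": "fricative", "h": "fricative",
    "m": "nasal", "n": "nasal",
    "l": "liquid", "r": "liquid",
    "j": "glide", "w": "glide",
}
_VOWELS = ("a", "e", "i", "o", "u", "y")
_CODAS = ("", "n", "s", "t", "l", "m", "r")

SYLLABLE_DURATION_S = 0.250
PLOSIVE_SILENCE_S = 0.020


@dataclass(frozen=True)
class Syllable:
    """A syllable with explicit (onset, nucleus, coda) phoneme annotation."""

    label: str
    onset: str
    nucleus: str
    coda: str = ""

    @property
    def manner(self) -> str:
        return _CONSONANTS[self.onset]

    @property
    def cv_pattern(self) -> str:
        return "C" + "V" + "C" * len(self.coda)

    @property
    def rime(self) -> str:
        return self.nucleus + self.coda

    @property
    def initial_phoneme(self) -> str:
        return self.onset

    @property
    def final_phoneme(self) -> str:
        return self.coda[-1] if self.coda else self.nucleus[-1]


@dataclass(frozen=True)
class SyllableToken:
    """One 250 ms stimulus slot.

    Tokens whose syllable starts with a plosive hold 230 ms of content
    preceded by 20 ms of silence (oral occlusion before the burst); all
    tokens occupy the full inter-onset interval.
    """

    label: str
    duration_s: float = SYLLABLE_DURATION_S
    is_plosive_onset: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("token duration must be positive")

    @property
    def content_duration_s(self) -> float:
        if self.is_plosive_onset:
            return self.duration_s - PLOSIVE_SILENCE_S
        return self.duration_s

    @property
    def silence_before_s(self) -> float:
        return PLOSIVE_SILENCE_S if self.is_plosive_onset else 0.0


@dataclass(frozen=True)
class WordEntry:
    syllable1: str
    syllable2: str
    frequency: int

    def __post_init__(self) -> None:
        if self.frequency < 0 or int(self.frequency) != self.frequency:
            raise ValueError("wordform frequency must be a non-negative integer")


@dataclass
class Lexicon:
    """Disyllabic wordforms with counts plus the syllable inventory."""

    entries: list[WordEntry]
    syllables: dict[str, Syllable]
    profile: str = "native_like"

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.syllable1 not in self.syllables or e.syllable2 not in self.syllables:
                raise ValueError(f"entry ({e.syllable1}, {e.syllable2}) uses syllables "
                                 "outside the inventory")

    @property
    def inventory(self) -> list[str]:
        return sorted(self.syllables)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class StimulusSequence:
    """An ordered syllable stream with unit (word) boundaries and onsets."""

    syllables: list[str]
    tokens: list[SyllableToken]
    onsets_s: np.ndarray
    unit_boundaries: np.ndarray  # indices of first syllable of each unit
    condition: str = ""
    target_index: int | None = None  # unit index of the repeated-syllable target
    block_index: int = 0
    syllable_rate_hz: float = 4.0

    def __post_init__(self) -> None:
        n = len(self.syllables)
        if n != 2 * len(self.unit_boundaries):
            raise ValueError("sequence length must be twice the number of units")
        dt = np.diff(self.onsets_s)
        if n > 1 and not np.allclose(dt, 1.0 / self.syllable_rate_hz):
            raise ValueError("onsets must be equally spaced at the inter-onset interval")
        if self.target_index is not None:
            i = 2 * int(self.target_index)
            if self.syllables[i] != self.syllables[i + 1]:
                raise ValueError("target unit must repeat the same syllable")

    @property
    def n_units(self) -> int:
        return len(self.unit_boundaries)

    @property
    def duration_s(self) -> float:
        return len(self.syllables) / self.syllable_rate_hz

    def units(self) -> list[tuple[str, str]]:
        return [(self.syllables[2 * i], self.syllables[2 * i + 1])
                for i in range(self.n_units)]


def _make_inventory(n: int, rng: np.random.Generator, p_coda: float = 0.4) -> list[Syllable]:
    """Draw ``n`` distinct CV(C) syllables."""
    cons = sorted(_CONSONANTS)
    out: dict[str, Syllable] = {}
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 100 * n + 1000:
            raise ValueError(f"cannot build {n} distinct syllables from the inventory")
        onset = cons[rng.integers(len(cons))]
        nucleus = _VOWELS[rng.integers(len(_VOWELS))]
        coda = _CODAS[rng.integers(1, len(_CODAS))] if rng.random() < p_coda else ""
        s = Syllable(onset + nucleus + coda, onset, nucleus, coda)
        out.setdefault(s.label, s)
    return list(out.values())


def _manner_consistent_consonant_map(rng: np.random.Generator) -> dict[str, str]:
    """Bijection on consonants that maps each manner class onto one other
    class of equal size (plosive<->fricative; nasal->liquid->glide->nasal)."""
    by_class: dict[str, list[str]] = {}
    for c in sorted(_CONSONANTS):
        by_class.setdefault(_CONSONANTS[c], []).append(c)
    class_map = {"plosive": "fricative", "fricative": "plosive",
                 "nasal": "liquid", "liquid": "glide", "glide": "nasal"}
    out: dict[str, str] = {}
    for src, dst in class_map.items():
        targets = list(rng.permutation(by_class[dst]))
        out.update(zip(by_class[src], targets))
    return out


def _zipf_frequencies(n: int, rng: np.random.Generator,
                      base: int = 2000, exponent: float = 0.8,
                      minimum: int = 10) -> np.ndarray:
    ranks = rng.permutation(n) + 1
    return np.maximum(minimum, np.round(base * ranks ** (-exponent))).astype(int)


def build_lexicon(n_words: int, profile: str = "native_like", seed: int = 0,
                  margin: float = 0.3) -> Lexicon:
    """Build a synthetic disyllabic lexicon.

    For the structured profiles each first syllable maps to a unique second
    syllable (disjoint position inventories), so the within-word identity
    transitional probability is 1 while between-word transitions follow the
    wordform-frequency marginal.  ``margin`` is the minimum required
    (within - between) identity-TP difference.

    For ``random``, word templates are position-balanced quasi-random draws
    from a shared inventory with equal frequency; sequence generation for
    this profile re-draws pseudo-word pairs freshly (see
    :func:`generate_sequence`), so the stream carries no transition cue.
    """
    if n_words < 4:
        raise ValueError("n_words must be at least 4")
    if profile not in ("native_like", "foreign_like", "random"):
        raise ValueError(f"unknown profile: {profile!r}")
    rng = np.random.default_rng(seed)

    if profile == "random":
        m = max(8, n_words // 3)
        syls = _make_inventory(m, rng)
        labels = [s.label for s in syls]
        # balanced position assignment: each syllable appears equally often
        # in each position, then shuffled (avoiding accidental repetitions,
        # which are reserved for targets)
        firsts = np.array([labels[i % m] for i in range(n_words)])
        seconds = np.array([labels[i % m] for i in range(n_words)])
        rng.shuffle(firsts)
        for _ in range(100):
            rng.shuffle(seconds)
            if not np.any(firsts == seconds):
                break
        else:  # deterministic fix-up of residual collisions
            for i in np.flatnonzero(firsts == seconds):
                j = (i + 1) % n_words
                seconds[i], seconds[j] = seconds[j], seconds[i]
        entries = [WordEntry(a, b, 100) for a, b in zip(firsts, seconds)]
        return Lexicon(entries, {s.label: s for s in syls}, profile)

    # structured profiles: the second syllable is a phoneme-level bijective
    # image of the first (consonants mapped between manner classes of equal
    # size, vowels and codas permuted), so every phonological projection of
    # the within-word transition is predictable from the first syllable
    onset_map = _manner_consistent_consonant_map(rng)
    vowel_map = dict(zip(_VOWELS, rng.permutation(_VOWELS)))
    coda_map = dict(zip(_CODAS, rng.permutation(_CODAS)))

    firsts_s = _make_inventory(n_words, rng)
    seconds_s = [Syllable(onset_map[s.onset] + vowel_map[s.nucleus] + coda_map[s.coda],
                          onset_map[s.onset], vowel_map[s.nucleus], coda_map[s.coda])
                 for s in firsts_s]
    freqs = _zipf_frequencies(n_words, rng)
    entries = [WordEntry(a.label, b.label, int(f))
               for a, b, f in zip(firsts_s, seconds_s, freqs)]
    syllables = {s.label: s for s in firsts_s + seconds_s}
    lex = Lexicon(entries, syllables, profile)

    from .corpus import expected_within_between_tp  # deferred: avoids cycle

    within, between = expected_within_between_tp(lex, "identity")
    if within - between < margin:
        raise ValueError(
            f"n_words={n_words} too small to separate within/between TPs by {margin}")
    return lex


def _token_for(lexicon: Lexicon, label: str, rate_hz: float) -> SyllableToken:
    syl = lexicon.syllables[label]
    return SyllableToken(label, 1.0 / rate_hz, is_plosive_onset=syl.manner == "plosive")


def generate_sequence(lexicon: Lexicon, n_units: int = 19, target: bool = False,
                      seed: int = 0, syllable_rate_hz: float = 4.0) -> StimulusSequence:
    """Concatenate randomly selected disyllabic units into one trial sequence.

    Units are drawn with probability proportional to wordform frequency
    (fresh position-balanced syllable pairs for the ``random`` profile); no
    unit immediately repeats.  With ``target``, one unit is replaced by a
    same-syllable repetition.
    """
    if not lexicon.entries:
        raise ValueError("lexicon is empty")
    rng = np.random.default_rng(seed)
    units: list[tuple[str, str]] = []
    # syllable repetitions are reserved for targets: neither a unit repeat
    # nor a repeated syllable across the unit boundary is allowed.  The
    # constraint is dropped after repeated failures (degenerate lexicons,
    # e.g. a single word, cannot satisfy it).
    misses = 0
    if lexicon.profile == "random":
        labels = lexicon.inventory
        while len(units) < n_units:
            a, b = rng.choice(labels, size=2, replace=False)
            if units and (units[-1] == (a, b) or units[-1][1] == a) and misses < 50:
                misses += 1
                continue
            misses = 0
            units.append((a, b))
    else:
        freqs = np.array([e.frequency for e in lexicon.entries], float)
        p = freqs / freqs.sum()
        while len(units) < n_units:
            e = lexicon.entries[rng.choice(len(lexicon.entries), p=p)]
            if units and (units[-1] == (e.syllable1, e.syllable2)
                          or units[-1][1] == e.syllable1) and misses < 50:
                misses += 1
                continue
            misses = 0
            units.append((e.syllable1, e.syllable2))

    target_index: int | None = None
    if target:
        target_index = int(rng.integers(n_units))
        s = lexicon.inventory[rng.integers(len(lexicon.inventory))]
        units[target_index] = (s, s)

    syllables = [s for u in units for s in u]
    tokens = [_token_for(lexicon, s, syllable_rate_hz) for s in syllables]
    onsets = np.arange(len(syllables)) / syllable_rate_hz
    return StimulusSequence(
        syllables=syllables, tokens=tokens, onsets_s=onsets,
        unit_boundaries=np.arange(0, len(syllables), 2),
        target_index=target_index, syllable_rate_hz=syllable_rate_hz)


def generate_experiment(lexicon_by_condition: Mapping[str, Lexicon],
                        n_trials: int = 210, target_fraction: float = 0.29,
                        n_blocks: int = 15, seed: int = 0,
                        n_units: int = 19) -> list[StimulusSequence]:
    """Generate a full session: equal trials per condition, interleaved blocks.

    Exactly ``round(target_fraction * n_trials)`` trials contain a
    repeated-syllable target, split equally across conditions (any remainder
    is assigned to conditions in sorted order).
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must be in [0, 1]")
    conds = sorted(lexicon_by_condition)
    n_cond = len(conds)
    if n_trials % n_cond:
        raise ValueError("n_trials must be divisible by the number of conditions")
    per_cond = n_trials // n_cond
    n_targets = round(target_fraction * n_trials)
    base, rem = divmod(n_targets, n_cond)

    rng = np.random.default_rng(seed)
    per_cond_trials: dict[str, list[StimulusSequence]] = {}
    for ci, cond in enumerate(conds):
        nt = base + (1 if ci < rem else 0)
        flags = np.zeros(per_cond, bool)
        flags[:nt] = True
        rng.shuffle(flags)
        trials = []
        for flag in flags:
            sub = int(rng.integers(2 ** 31))
            s = generate_sequence(lexicon_by_condition[cond], n_units=n_units,
                                  target=bool(flag), seed=sub)
            s.condition = cond
            trials.append(s)
        per_cond_trials[cond] = trials

    # interleave conditions within blocks, in presentation order
    out: list[StimulusSequence] = []
    iters = {c: iter(t) for c, t in per_cond_trials.items()}
    per_block = n_trials // n_blocks
    for b in range(n_blocks):
        block: list[StimulusSequence] = []
        for i in range(per_block):
            cond = conds[(b * per_block + i) % n_cond]
            block.append(next(iters[cond]))
        for s in block:
            s.block_index = b
            out.append(s)
    # distribute any remainder trials into the last block
    for c in conds:
        for s in iters[c]:
            s.block_index = n_blocks - 1
            out.append(s)
    return out
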