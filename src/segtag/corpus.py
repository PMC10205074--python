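"""Syllable-to-syllable transitional probability (TP) analysis.

TP(e2 | e1) = Frequency(pair e1-e2) / Frequency(e1), computed on a bigram
table for one of six phonological measurements: syllable identity, syllable
CV pattern, onset phoneme, onset-phoneme manner of articulation, rime, and
the phoneme pair across the syllable boundary.  Within-unit (word) and
between-unit transitions of stimulus sequences are scored against a
reference table and contrasted with a two-sided Mann-Whitney test with
Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .lexicon import Lexicon, StimulusSequence, Syllable

__all__ = [
    "MEASUREMENTS",
    "BigramTable",
    "TPContrast",
    "project_transition",
    "transitional_probability",
    "laplace_smooth",
    "expected_bigram_table",
    "count_bigram_table",
    "within_between_contrast",
    "select_words",
    "mann_whitney",
]

MEASUREMENTS = ("identity", "cv_pattern", "onset", "manner", "rime",
                "cross_boundary_phoneme")


def project_transition(s1: Syllable, s2: Syllable, measurement: str) -> tuple[str, str]:
    """Project a syllable transition onto a phonological measurement.

    All measurements apply the same projection to both syllables except
    ``cross_boundary_phoneme``, which pairs the final phoneme of the first
    syllable with the initial phoneme of the second.
    """
    if measurement == "identity":
        return s1.label, s2.label
    if measurement == "cv_pattern":
        return s1.cv_pattern, s2.cv_pattern
    if measurement == "onset":
        return s1.onset, s2.onset
    if measurement == "manner":
        return s1.manner, s2.manner
    if measurement == "rime":
        return s1.rime, s2.rime
    if measurement == "cross_boundary_phoneme":
        return s1.final_phoneme, s2.initial_phoneme
    raise ValueError(f"unknown measurement: {measurement!r}")


@dataclass
class BigramTable:
    """Pair and first-element frequencies for one measurement.

    Counts may be expected (real-valued) frequencies; ``unit_freq`` is kept
    consistent with the row sums of ``pair_freq``.
    """

    pair_freq: dict[tuple[str, str], float]
    measurement: str = "identity"
    unit_freq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.pair_freq.values()):
            raise ValueError("bigram counts must be non-negative")
        if not self.unit_freq:
            self.unit_freq = self._row_sums()

    def _row_sums(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (e1, _), c in self.pair_freq.items():
            out[e1] = out.get(e1, 0.0) + c
        return out

    @property
    def first_vocabulary(self) -> list[str]:
        return sorted({e1 for e1, _ in self.pair_freq})

    @property
    def second_vocabulary(self) -> list[str]:
        return sorted({e2 for _, e2 in self.pair_freq})


def transitional_probability(table: BigramTable, e1: str, e2: str) -> float:
    """TP(e2 | e1) = pair frequency / first-element frequency."""
    denom = table.unit_freq.get(e1, 0.0)
    if denom <= 0:
        raise KeyError(f"element {e1!r} has zero frequency; cannot condition on it")
    return table.pair_freq.get((e1, e2), 0.0) / denom


def laplace_smooth(table: BigramTable, alpha: float = 1.0) -> BigramTable:
    """Add-``alpha`` smoothing over the observed first x second vocabularies.

    Every pair in the product of the observed vocabularies receives at
    least ``alpha``; unit frequencies are recomputed as row sums, so TPs
    stay in [0, 1] and sum to 1 over the smoothed continuation set.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    pairs = {(a, b): table.pair_freq.get((a, b), 0.0) + alpha
             for a in table.first_vocabulary for b in table.second_vocabulary}
    return BigramTable(pairs, table.measurement)


def expected_bigram_table(lexicon: Lexicon, measurement: str = "identity",
                          total: float = 1e6) -> BigramTable:
    """Expected stream bigram statistics of a lexicon's generative model.

    For structured profiles the syllable stream concatenates
    frequency-weighted word draws: within-word bigrams occur with the word
    probability and between-word bigrams with the product of the word-final
    and word-initial marginals (each class carrying half the transitions).
    For the ``random`` profile both positions are uniform independent draws
    from the inventory (excluding accidental repetitions).  ``total`` only
    sets the count scale.
    """
    syl = lexicon.syllables
    pairs: dict[tuple[str, str], float] = {}

    def add(a: Syllable, b: Syllable, mass: float) -> None:
        key = project_transition(a, b, measurement)
        pairs[key] = pairs.get(key, 0.0) + mass

    if lexicon.profile == "random":
        labels = lexicon.inventory
        m = len(labels)
        w = 1.0 / (m * (m - 1))  # uniform over ordered non-identical pairs;
        # immediate repetitions are excluded both within pseudo-words and
        # across boundaries (repetitions are reserved for targets)
        for a in labels:
            for b in labels:
                if a == b:
                    continue
                add(syl[a], syl[b], 0.5 * total * w)      # within a pseudo-word
                add(syl[a], syl[b], 0.5 * total * w)      # across the boundary
        return BigramTable(pairs, measurement)

    freqs = np.array([e.frequency for e in lexicon.entries], float)
    p = freqs / freqs.sum()
    for e, pw in zip(lexicon.entries, p):
        add(syl[e.syllable1], syl[e.syllable2], 0.5 * total * pw)
    for e1, p1 in zip(lexicon.entries, p):       # end of word e1
        for e2, p2 in zip(lexicon.entries, p):   # start of word e2
            add(syl[e1.syllable2], syl[e2.syllable1], 0.5 * total * p1 * p2)
    return BigramTable(pairs, measurement)


def expected_within_between_tp(lexicon: Lexicon, measurement: str = "identity",
                               table: BigramTable | None = None
                               ) -> tuple[float, float]:
    """Expected mean within- and between-unit TPs under the stream model.

    Averages are weighted by the occurrence probability of each transition
    in the generated stream (word probability for within; product of
    word-final and word-initial probabilities for between).
    """
    if table is None:
        table = expected_bigram_table(lexicon, measurement)
    syl = lexicon.syllables

    def tp(a: str, b: str) -> float:
        s1, s2 = syl[a], syl[b]
        return transitional_probability(table, *project_transition(s1, s2, measurement))

    if lexicon.profile == "random":
        labels = lexicon.inventory
        m = len(labels)
        vals = [tp(a, b) for a in labels for b in labels if a != b]
        v = float(np.mean(vals))
        return v, v
    freqs = np.array([e.frequency for e in lexicon.entries], float)
    p = freqs / freqs.sum()
    within = float(sum(pw * tp(e.syllable1, e.syllable2)
                       for e, pw in zip(lexicon.entries, p)))
    between = float(sum(p1 * p2 * tp(e1.syllable2, e2.syllable1)
                        for e1, p1 in zip(lexicon.entries, p)
                        for e2, p2 in zip(lexicon.entries, p)))
    return within, between


def count_bigram_table(sequences: list[StimulusSequence], lexicon: Lexicon,
                       measurement: str = "identity") -> BigramTable:
    """Exhaustive bigram counting over the concatenated syllable streams."""
    syl = lexicon.syllables
    pairs: dict[tuple[str, str], float] = {}
    for s in sequences:
        for a, b in zip(s.syllables[:-1], s.syllables[1:]):
            key = project_transition(syl[a], syl[b], measurement)
            pairs[key] = pairs.get(key, 0.0) + 1.0
    return BigramTable(pairs, measurement)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact (exhaustive permutation) null when both samples have at most 8
    observations; normal approximation with tie correction otherwise.
    Degenerate inputs (all values identical) return p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(x.size * y.size / 2), 1.0
    if x.size <= 8 and y.size <= 8:
        method = stats.PermutationMethod(n_resamples=np.inf)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TPContrast:
    """Within- vs between-word TP contrast for one measurement."""

    within: np.ndarray
    between: np.ndarray
    measurement: str
    condition: str
    p_value: float          # Bonferroni-corrected
    p_uncorrected: float
    u_statistic: float

    @property
    def diff(self) -> float:
        return float(np.mean(self.within) - np.mean(self.between))


def _drop_outliers(values: np.ndarray, n_sd: float = 2.5) -> np.ndarray:
    mu, sd = values.mean(), values.std()
    if sd == 0:
        return values
    return values[values <= mu + n_sd * sd]


def within_between_contrast(sequences: list[StimulusSequence], lexicon: Lexicon,
                            measurement: str, table: BigramTable | None = None,
                            alpha: float = 1.0, n_tests: int = 1,
                            exclude_targets: bool = True,
                            drop_outliers: bool = False) -> TPContrast:
    """Score and contrast within- vs between-unit transitions of sequences.

    Each transition is projected onto ``measurement`` and scored by its TP
    under the (Laplace-smoothed) reference ``table``; by default the
    analytic expected table of the lexicon's generative model.  The
    two-sided Mann-Whitney p value is Bonferroni-corrected by ``n_tests``
    (the declared family size).
    """
    if measurement not in MEASUREMENTS:
        raise ValueError(f"unknown measurement: {measurement!r}")
    conds = {s.condition for s in sequences}
    if len(conds) > 1:
        raise ValueError("sequences must share one condition")
    syl = lexicon.syllables
    for s in sequences:
        for lab in s.syllables:
            if lab not in syl:
                raise KeyError(f"syllable {lab!r} has no phoneme annotation in the lexicon")
    if table is None:
        table = expected_bigram_table(lexicon, measurement)
    table = laplace_smooth(table, alpha)

    within, between = [], []
    for s in sequences:
        for u in range(s.n_units):
            if exclude_targets and u == s.target_index:
                continue
            a, b = syl[s.syllables[2 * u]], syl[s.syllables[2 * u + 1]]
            within.append(transitional_probability(table, *project_transition(a, b, measurement)))
        for u in range(s.n_units - 1):
            if exclude_targets and s.target_index in (u, u + 1):
                continue
            a, b = syl[s.syllables[2 * u + 1]], syl[s.syllables[2 * u + 2]]
            between.append(transitional_probability(table, *project_transition(a, b, measurement)))

    w = np.asarray(within, float)
    b = np.asarray(between, float)
    if drop_outliers:
        w, b = _drop_outliers(w), _drop_outliers(b)
    u_stat, p = mann_whitney(w, b)
    return TPContrast(w, b, measurement, next(iter(conds)) if conds else "",
                      p_value=min(1.0, p * n_tests), p_uncorrected=p,
                      u_statistic=u_stat)


def syllable_transition_probability(lexicon: Lexicon, entry_index: int) -> float:
    """STP of a wordform: its frequency over the summed frequencies of all
    wordforms sharing its first syllable."""
    e = lexicon.entries[entry_index]
    denom = sum(w.frequency for w in lexicon.entries if w.syllable1 == e.syllable1)
    return e.frequency / denom if denom else 0.0


def select_words(lexicon: Lexicon, min_frequency: int = 10,
                 min_stp: float = 0.003) -> Lexicon:
    """Word-selection filter: keep high-frequency, high-STP wordforms."""
    kept = [e for i, e in enumerate(lexicon.entries)
            if e.frequency >= min_frequency
            and syllable_transition_probability(lexicon, i) >= min_stp]
    return Lexicon(kept, dict(lexicon.syllables), lexicon.profile)
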