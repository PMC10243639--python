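"""Phoneme alignments, glimpse ratios, and phonetic/word-onset regressors.

A forced alignment provides, for each talker, a tier of phoneme intervals
(label, start, end, word membership).  Each phoneme maps to 22 binary
articulatory/acoustic features (voicing, manner, place, vowel dimensions).
In a two-talker mixture, each phoneme is partially audible: its *glimpse
ratio* is the fraction of its time-frequency cells (on a 100-band
spectrogram) where the talker's energy exceeds the competing background by at
least a threshold SNR.  Multiplying the binary features by the glimpse ratio
(and its complement, the mask ratio) splits the phonetic representation into
glimpsed and masked regressors that sum back to the binary original.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectrogram import BandSpectrogram

#: The 22 articulatory/acoustic feature names, in canonical column order.
FEATURE_NAMES: tuple[str, ...] = (
    "voiced", "unvoiced", "sonorant", "syllabic", "consonantal", "approximant",
    "plosive", "strident", "coronal", "anterior", "dorsal", "front", "back",
    "high", "low", "nasal", "fricative", "obstruent", "bilabial", "labiodental",
    "alveolar", "velar",
)


@dataclass(frozen=True)
class PhonemeInterval:
    label: str
    start_s: float
    end_s: float
    word_index: int


@dataclass
class PhonemeTier:
    """Sorted, non-overlapping phoneme intervals with word membership."""

    intervals: list[PhonemeInterval]
    total_duration_s: float

    def __post_init__(self) -> None:
        prev_end = 0.0
        prev_word = -1
        for iv in self.intervals:
            if iv.end_s <= iv.start_s:
                raise ValueError(f"interval {iv.label} has end <= start")
            if iv.start_s < prev_end - 1e-9:
                raise ValueError("intervals overlap or are unsorted")
            if iv.word_index < prev_word:
                raise ValueError("word_index must be non-decreasing")
            prev_end = iv.end_s
            prev_word = iv.word_index

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def labels(self) -> list[str]:
        return [iv.label for iv in self.intervals]

    @property
    def n_words(self) -> int:
        return len({iv.word_index for iv in self.intervals})

    def frame_span(self, iv: PhonemeInterval, frame_rate_hz: float) -> tuple[int, int]:
        """Half-open frame range [round(start*rate), round(end*rate)) owned by ``iv``."""
        a = int(round(iv.start_s * frame_rate_hz))
        b = int(round(iv.end_s * frame_rate_hz))
        return a, b


class PhoneticFeatureMap:
    """Mapping from phoneme label to its 22-bit feature vector."""

    def __init__(self, mapping: dict[str, np.ndarray],
                 feature_names: tuple[str, ...] = FEATURE_NAMES):
        self.feature_names = tuple(feature_names)
        self.mapping = {
            k: np.asarray(v, dtype=float).ravel() for k, v in mapping.items()
        }
        for k, v in self.mapping.items():
            if v.size != len(self.feature_names):
                raise ValueError(f"feature vector for {k} has wrong length")
            if not np.all(np.isin(v, (0.0, 1.0))):
                raise ValueError(f"feature vector for {k} is not binary")

    def __contains__(self, label: str) -> bool:
        return label in self.mapping

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.mapping[label]
        except KeyError:
            raise KeyError(f"phoneme label {label!r} missing from feature map") from None

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def features_of(self, label: str) -> set[str]:
        vec = self[label]
        return {f for f, v in zip(self.feature_names, vec) if v}

    @classmethod
    def load_arpabet(cls) -> "PhoneticFeatureMap":
        """Load the shipped ARPABET -> 22-feature table."""
        ref = importlib.resources.files("glimpsetrf.data") / "arpabet_features.tsv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", index_col="phoneme")
        if tuple(df.columns) != FEATURE_NAMES:
            raise RuntimeError("packaged feature table has unexpected columns")
        return cls({ph: df.loc[ph].to_numpy(dtype=float) for ph in df.index})


@dataclass
class GlimpseRatios:
    """Per-phoneme glimpse/mask ratios at one SNR threshold (ratios sum to 1)."""

    ratio_glimpse: np.ndarray
    snr_threshold_db: float

    @property
    def ratio_mask(self) -> np.ndarray:
        return 1.0 - self.ratio_glimpse


def compute_glimpse_ratios(
    talker_spec: BandSpectrogram,
    background_spec: BandSpectrogram,
    tier: PhonemeTier,
    snr_threshold_db: float = -4.0,
    scale: str = "magnitude",
    denominator: str = "all",
) -> GlimpseRatios:
    """Fraction of each phoneme's time-frequency cells that are glimpsed.

    A cell (frame, band) is glimpsed when
    ``talker >= background * 10**(snr_db / 20)`` (magnitude convention; pass
    ``scale="power"`` for ``10**(snr_db / 10)``).  Cells where both talker and
    background are zero count as glimpsed via the ``>=`` comparison.

    Parameters
    ----------
    denominator : "all" counts every cell of the interval (default); "nonzero"
        restricts the denominator to cells where the talker has energy.
    """
    if talker_spec.values.shape != background_spec.values.shape:
        raise ValueError("talker and background spectrograms must share shape")
    if not np.isfinite(snr_threshold_db):
        raise ValueError("snr threshold must be finite")
    if scale not in ("magnitude", "power"):
        raise ValueError("scale must be 'magnitude' or 'power'")
    factor = 10.0 ** (snr_threshold_db / (20.0 if scale == "magnitude" else 10.0))
    rate = talker_spec.frame_rate_hz
    n_frames = talker_spec.n_frames

    glimpsed_cells = talker_spec.values >= background_spec.values * factor
    ratios = np.empty(len(tier))
    for i, iv in enumerate(tier.intervals):
        a, b = tier.frame_span(iv, rate)
        if a < 0 or b > n_frames:
            raise ValueError(f"interval {iv.label} lies outside the spectrogram")
        if b <= a:
            raise ValueError(f"interval {iv.label} is empty after frame quantization")
        cells = glimpsed_cells[a:b]
        if denominator == "all":
            ratios[i] = cells.mean()
        else:
            active = talker_spec.values[a:b] > 0
            n_active = active.sum()
            ratios[i] = (cells & active).sum() / n_active if n_active else 0.0
    return GlimpseRatios(ratio_glimpse=ratios, snr_threshold_db=snr_threshold_db)


def binary_feature_matrix(
    tier: PhonemeTier,
    fmap: PhoneticFeatureMap,
    frame_rate_hz: float = 100.0,
    n_frames: int | None = None,
) -> np.ndarray:
    """Time x 22 binary phonetic feature matrix (1 for the phoneme's duration)."""
    if n_frames is None:
        n_frames = int(round(tier.total_duration_s * frame_rate_hz))
    out = np.zeros((n_frames, fmap.n_features))
    for iv in tier.intervals:
        a, b = tier.frame_span(iv, frame_rate_hz)
        out[a:b] = fmap[iv.label]
    return out


def build_phonetic_regressors(
    tier: PhonemeTier,
    fmap: PhoneticFeatureMap,
    ratios: GlimpseRatios,
    frame_rate_hz: float = 100.0,
    n_frames: int | None = None,
) -> dict[str, np.ndarray]:
    """Glimpsed/masked phonetic-feature and phoneme-onset regressors.

    For each phoneme the binary feature vector is scaled by the phoneme's
    glimpse ratio (glimpsed copy) and mask ratio (masked copy); the two copies
    sum to the binary features exactly.  Onset regressors are single-frame
    impulses at each phoneme start carrying the same ratios.
    """
    if len(ratios.ratio_glimpse) != len(tier):
        raise ValueError("ratios and tier length mismatch")
    for lab in tier.labels:
        if lab not in fmap:
            raise KeyError(f"phoneme label {lab!r} missing from feature map")
    if n_frames is None:
        n_frames = int(round(tier.total_duration_s * frame_rate_hz))
    k = fmap.n_features
    glim = np.zeros((n_frames, k))
    mask = np.zeros((n_frames, k))
    glim_on = np.zeros((n_frames, 1))
    mask_on = np.zeros((n_frames, 1))
    for iv, rg in zip(tier.intervals, ratios.ratio_glimpse):
        a, b = tier.frame_span(iv, frame_rate_hz)
        vec = fmap[iv.label]
        glim[a:b] = rg * vec
        mask[a:b] = (1.0 - rg) * vec
        glim_on[a, 0] = rg
        mask_on[a, 0] = 1.0 - rg
    return {
        "glimpsed": glim,
        "masked": mask,
        "glimpsed_onsets": glim_on,
        "masked_onsets": mask_on,
    }


def word_onset_regressor(
    tier: PhonemeTier,
    frame_rate_hz: float = 100.0,
    n_frames: int | None = None,
) -> np.ndarray:
    """Binary impulse at the start frame of each word-initial phoneme."""
    if n_frames is None:
        n_frames = int(round(tier.total_duration_s * frame_rate_hz))
    out = np.zeros((n_frames, 1))
    seen: set[int] = set()
    for iv in tier.intervals:
        if iv.word_index not in seen:
            seen.add(iv.word_index)
            a, _ = tier.frame_span(iv, frame_rate_hz)
            out[a, 0] = 1.0
    return out


def shuffle_feature_mapping(
    fmap: PhoneticFeatureMap, seed: int | np.random.Generator = 0
) -> PhoneticFeatureMap:
    """Permute feature vectors across phoneme labels (phonetic null).

    Every phoneme still maps consistently to one vector, so phoneme identity
    and timing are preserved while articulatory content is scrambled.
    """
    labels = sorted(fmap.mapping)
    if len(labels) < 2:
        raise ValueError("need at least 2 phonemes to shuffle the mapping")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(labels))
    return PhoneticFeatureMap(
        {lab: fmap.mapping[labels[j]] for lab, j in zip(labels, perm)},
        fmap.feature_names,
    )


def shuffle_word_onsets(
    tier: PhonemeTier,
    frame_rate_hz: float = 100.0,
    seed: int | np.random.Generator = 0,
    n_frames: int | None = None,
) -> np.ndarray:
    """One impulse per word at a uniformly chosen phoneme onset of that word."""
    if n_frames is None:
        n_frames = int(round(tier.total_duration_s * frame_rate_hz))
    rng = np.random.default_rng(seed)
    by_word: dict[int, list[PhonemeInterval]] = {}
    for iv in tier.intervals:
        by_word.setdefault(iv.word_index, []).append(iv)
    out = np.zeros((n_frames, 1))
    for w in sorted(by_word):
        iv = by_word[w][rng.integers(len(by_word[w]))]
        a, _ = tier.frame_span(iv, frame_rate_hz)
        out[a, 0] = 1.0
    return out


# ---------------------------------------------------------------------------
# Alignment readers


def read_alignment_tsv(path) -> PhonemeTier:
    """Read a tab-separated alignment: columns label, start_s, end_s, word_id."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "start_s", "end_s", "word_id"}
    if not required <= set(df.columns):
        raise ValueError(f"alignment file needs columns {sorted(required)}")
    df = df.sort_values("start_s")
    intervals = [
        PhonemeInterval(str(r.label), float(r.start_s), float(r.end_s), int(r.word_id))
        for r in df.itertuples()
    ]
    return PhonemeTier(intervals, total_duration_s=float(df["end_s"].max()))


def write_alignment_tsv(tier: PhonemeTier, path) -> None:
    pd.DataFrame(
        [(iv.label, iv.start_s, iv.end_s, iv.word_index) for iv in tier.intervals],
        columns=["label", "start_s", "end_s", "word_id"],
    ).to_csv(path, sep="\t", index=False)


def _parse_textgrid_tiers(text: str) -> dict[str, list[tuple[float, float, str]]]:
    # minimal long-format TextGrid interval-tier parser
    import re

    tiers: dict[str, list[tuple[float, float, str]]] = {}
    chunks = re.split(r"item \[\d+\]:", text)[1:]
    for chunk in chunks:
        m = re.search(r'name\s*=\s*"([^"]*)"', chunk)
        if m is None or 'class = "IntervalTier"' not in chunk:
            continue
        name = m.group(1)
        ivs = []
        for im in re.finditer(
            r"intervals \[\d+\]:\s*xmin\s*=\s*([\d.eE+-]+)\s*"
            r"xmax\s*=\s*([\d.eE+-]+)\s*text\s*=\s*\"([^\"]*)\"",
            chunk,
        ):
            ivs.append((float(im.group(1)), float(im.group(2)), im.group(3).strip()))
        tiers[name] = ivs
    return tiers


def read_textgrid(path, phone_tier: str = "phones", word_tier: str = "words") -> PhonemeTier:
    """Read a Praat long-format TextGrid with phone and word interval tiers.

    Empty/"sp"/"sil" labels are treated as silence and dropped; word indices
    are assigned by containment of each phone's midpoint in a word interval.
    """
    with open(path) as f:
        tiers = _parse_textgrid_tiers(f.read())
    if phone_tier not in tiers:
        raise ValueError(f"TextGrid has no interval tier named {phone_tier!r}")
    silence = {"", "sp", "sil", "spn"}
    words = [iv for iv in tiers.get(word_tier, []) if iv[2].lower() not in silence]
    intervals = []
    total = 0.0
    widx = 0
    for xmin, xmax, label in tiers[phone_tier]:
        total = max(total, xmax)
        if label.lower() in silence:
            continue
        mid = 0.5 * (xmin + xmax)
        for j, (wmin, wmax, _) in enumerate(words):
            if wmin <= mid < wmax:
                widx = j
                break
        intervals.append(PhonemeInterval(label.upper(), xmin, xmax, widx))
    return PhonemeTier(intervals, total_duration_s=total)
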