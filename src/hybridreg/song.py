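"""Song phenotyping: segmentation, acoustic features, syllable-similarity
matrices (SSM) and motif/repetition transition scores.

A song is treated as an ordered list of syllables.  An SSM is the
round-robin similarity of all syllables of one song against all
syllables of another (or the same) song, with singing order preserved.
Binarizing the SSM at a threshold (default 0.595) and sliding a 2x2
window over it turns sequential structure into two rates: the *motif*
rate counts windows where consecutive syllables match pairwise but not
crosswise (the identity pattern [[1,0],[0,1]]), and the *repetition*
rate counts windows where all four comparisons match ([[1,1],[1,1]]).
Songs built from repeated multi-syllable motifs score high on the
former; songs of repeated single syllables score high on the latter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

FEATURE_NAMES = [
    "duration_ms", "gap_to_next_ms", "mean_pitch_hz", "pitch_goodness",
    "wiener_entropy", "entropy_variance", "mean_am", "am_variance",
    "mean_fm_deg", "fm_variance",
]


@dataclass
class Syllable:
    """One segmented syllable: boundaries, per-frame feature trajectory
    and summary acoustic features."""
    onset_s: float
    offset_s: float
    trajectory: np.ndarray | None = None  # (frames, features)
    features: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_syllables(waveform: np.ndarray, rate: int,
                      threshold_frac: float = 0.05,
                      min_duration_s: float = 0.02,
                      min_gap_s: float = 0.01,
                      smooth_s: float = 0.002) -> list[Syllable]:
    """Amplitude-envelope segmentation of a mono waveform.

    The envelope (moving RMS over ``smooth_s``) is thresholded at
    ``threshold_frac`` of its peak; above-threshold runs closer than
    ``min_gap_s`` are merged and runs shorter than ``min_duration_s``
    are dropped.  Silent input yields an empty list.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1:
        raise ValueError("waveform must be mono")
    if w.size == 0 or np.max(np.abs(w)) == 0:
        return []
    win = max(int(smooth_s * rate), 1)
    env = np.sqrt(np.convolve(w ** 2, np.ones(win) / win, mode="same"))
    above = env >= threshold_frac * env.max()
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]])

    # merge runs separated by less than min_gap
    merged = [[run_starts[0], run_ends[0]]]
    min_gap_n = int(min_gap_s * rate)
    for s, e in zip(run_starts[1:], run_ends[1:]):
        if s - merged[-1][1] <= min_gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_dur_n = int(min_duration_s * rate)
    return [Syllable(onset_s=s / rate, offset_s=e / rate)
            for s, e in merged if e - s >= min_dur_n]


# ---------------------------------------------------------------------------
# Acoustic features
# ---------------------------------------------------------------------------

def spectrogram(waveform: np.ndarray, rate: int, window: int = 1024,
                hop_s: float = 0.001) -> tuple[np.ndarray, np.ndarray,
                                               np.ndarray]:
    """Power spectrogram (freqs, times, power[freq, time])."""
    hop = max(int(hop_s * rate), 1)
    nper = min(window, len(waveform))
    freqs, times, sxx = signal.spectrogram(
        waveform, fs=rate, nperseg=nper, noverlap=nper - hop,
        window="hann", mode="psd")
    return freqs, times, sxx


def wiener_entropy(power_frames: np.ndarray) -> np.ndarray:
    """Per-frame log(geometric mean / arithmetic mean) of spectral power.

    0 for a flat (white) spectrum, increasingly negative for tonal sound.
    """
    p = np.asarray(power_frames, dtype=float) + 1e-300
    log_gm = np.mean(np.log(p), axis=0)
    log_am = np.log(np.mean(p, axis=0))
    return log_gm - log_am


def _cepstral_pitch(power: np.ndarray, freqs: np.ndarray, rate: int,
                    fmin: float = 300.0, fmax: float = 4000.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame pitch (Hz) and pitch goodness from the real cepstrum."""
    log_p = np.log(power + 1e-300)
    cep = np.fft.irfft(log_p, axis=0)
    n = cep.shape[0]
    # quefrency resolution: the spectrogram's frequency bins span 0..fs/2
    # over len(freqs) bins, so the cepstrum sample step is 1/(2*fs_bin_span)
    span = freqs[-1] - freqs[0] if len(freqs) > 1 else rate / 2
    dq = 1.0 / (2.0 * span)
    quef = np.arange(n) * dq
    lo = np.searchsorted(quef, 1.0 / fmax)
    hi = np.searchsorted(quef, 1.0 / fmin)
    lo = max(lo, 1)
    hi = max(hi, lo + 1)
    band = cep[lo:hi]
    peak = np.argmax(band, axis=0)
    goodness = band[peak, np.arange(band.shape[1])]
    pitch = 1.0 / quef[lo + peak]
    return pitch, goodness


def acoustic_features(power: np.ndarray, freqs: np.ndarray, rate: int,
                      duration_s: float, gap_to_next_s: float = np.nan
                      ) -> dict:
    """Summary acoustic features of one syllable's power spectrogram.

    ``power`` is (freq x time).  Wiener entropy is the log ratio of
    geometric to arithmetic spectral mean; AM is the frame-to-frame
    derivative of log power; FM is the angle (degrees) of the spectral
    time-derivative against the frequency-derivative; pitch and pitch
    goodness come from the cepstral peak.  Single-frame input flags the
    variances as NaN.
    """
    power = np.atleast_2d(power)
    n_frames = power.shape[1]
    went = wiener_entropy(power)
    pitch, goodness = _cepstral_pitch(power, freqs, rate)

    feats = {
        "duration_ms": duration_s * 1000.0,
        "gap_to_next_ms": gap_to_next_s * 1000.0,
        "mean_pitch_hz": float(np.mean(pitch)),
        "pitch_goodness": float(np.mean(goodness)),
        "wiener_entropy": float(np.mean(went)),
    }
    if n_frames < 2:
        feats.update({"entropy_variance": np.nan, "mean_am": np.nan,
                      "am_variance": np.nan, "mean_fm_deg": np.nan,
                      "fm_variance": np.nan})
        return feats

    log_power_sum = np.log(power.sum(axis=0) + 1e-300)
    am = np.diff(log_power_sum)
    dt = np.diff(power, axis=1)
    df = np.diff(power, axis=0)[:, 1:]
    # per-frame FM: angle between temporal and spectral energy change
    num = np.sqrt(np.mean(dt[1:, :] ** 2, axis=0))
    den = np.sqrt(np.mean(df ** 2, axis=0)) + 1e-300
    fm = np.degrees(np.arctan(num / den))

    feats.update({
        "entropy_variance": float(np.var(went)),
        "mean_am": float(np.mean(am)),
        "am_variance": float(np.var(am)),
        "mean_fm_deg": float(np.mean(fm)),
        "fm_variance": float(np.var(fm)),
    })
    return feats


def extract_syllables(waveform: np.ndarray, rate: int,
                      **segment_kw) -> list[Syllable]:
    """Segment a waveform and attach spectrogram trajectories and
    summary features to each syllable."""
    syllables = segment_syllables(waveform, rate, **segment_kw)
    for i, syl in enumerate(syllables):
        start = int(syl.onset_s * rate)
        end = int(syl.offset_s * rate)
        freqs, _, power = spectrogram(waveform[start:end], rate)
        gap = (syllables[i + 1].onset_s - syl.offset_s
               if i + 1 < len(syllables) else np.nan)
        syl.trajectory = power.T  # frames x freq bins
        syl.features = acoustic_features(power, freqs, rate,
                                         syl.duration_s, gap)
    return syllables


# ---------------------------------------------------------------------------
# Similarity and the SSM
# ---------------------------------------------------------------------------

def _resample_trajectory(traj: np.ndarray, n_frames: int) -> np.ndarray:
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    if traj.shape[0] == n_frames:
        return traj
    old = np.linspace(0.0, 1.0, traj.shape[0])
    new = np.linspace(0.0, 1.0, n_frames)
    return np.stack([np.interp(new, old, traj[:, j])
                     for j in range(traj.shape[1])], axis=1)


def syllable_similarity(traj_a: np.ndarray, traj_b: np.ndarray,
                        n_frames: int = 20) -> float:
    """Similarity in [0, 1] between two feature trajectories.

    Both trajectories are linearly time-resampled to ``n_frames``,
    flattened, and Pearson-correlated; r is mapped affinely from [-1, 1]
    to [0, 1].  Identical syllables score 1; independent ones centre on
    0.5.  Zero-variance trajectories compare by near-equality.
    """
    a = _resample_trajectory(traj_a, n_frames).ravel()
    b = _resample_trajectory(traj_b, n_frames).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty feature trajectory")
    if a.shape != b.shape:
        raise ValueError("trajectories disagree in feature dimension")
    if np.std(a) == 0 or np.std(b) == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float((r + 1.0) / 2.0)


@dataclass
class SimilarityMatrix:
    """Ordered syllable x syllable similarity scores with binarized form."""
    scores: np.ndarray
    threshold: float = 0.595
    binary: np.ndarray = None

    def __post_init__(self):
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.binary = (self.scores >= self.threshold).astype(int)


def build_ssm(syllables_a, syllables_b=None,
              threshold: float = 0.595, n_frames: int = 20
              ) -> SimilarityMatrix:
    """Round-robin SSM between two songs (or a song against itself).

    Accepts lists of :class:`Syllable` (using their trajectories) or raw
    trajectory arrays; the singing order of both songs is preserved.
    """
    def trajs(syls):
        out = []
        for s in syls:
            out.append(s.trajectory if isinstance(s, Syllable) else s)
        return out

    ta = trajs(syllables_a)
    tb = ta if syllables_b is None else trajs(syllables_b)
    if not ta or not tb:
        raise ValueError("cannot build an SSM from an empty song")
    scores = np.empty((len(ta), len(tb)))
    for i, a in enumerate(ta):
        for j, b in enumerate(tb):
            scores[i, j] = syllable_similarity(a, b, n_frames=n_frames)
    return SimilarityMatrix(scores, threshold=threshold)


@dataclass
class TransitionScores:
    motif_pct: float
    repetition_pct: float


def transition_scores(ssm: SimilarityMatrix) -> TransitionScores:
    """Motif and repetition rates from 2x2 windows of the binarized SSM.

    Every (n1-1) x (n2-1) window position is inspected (stride 1, no
    wraparound).  Motif pattern: [[1,0],[0,1]] — consecutive syllables
    match pairwise but not crosswise.  Repetition pattern: all ones.
    Rates are percentages of all windows.
    """
    b = ssm.binary
    if b.shape[0] < 2 or b.shape[1] < 2:
        raise ValueError("binary SSM must be at least 2x2")
    tl = b[:-1, :-1]
    tr = b[:-1, 1:]
    bl = b[1:, :-1]
    br = b[1:, 1:]
    motif = (tl == 1) & (br == 1) & (tr == 0) & (bl == 0)
    repetition = (tl == 1) & (br == 1) & (tr == 1) & (bl == 1)
    total = motif.size
    return TransitionScores(motif_pct=100.0 * motif.sum() / total,
                            repetition_pct=100.0 * repetition.sum() / total)


# ---------------------------------------------------------------------------
# Phenotype-expression correlation
# ---------------------------------------------------------------------------

def correlate_phenotype(expr_or_ase, song_param) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) across paired individuals."""
    x = np.asarray(expr_or_ase, dtype=float)
    y = np.asarray(song_param, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_table(values: pd.DataFrame, song_params: pd.DataFrame
                      ) -> pd.DataFrame:
    """All pairwise correlations between expression/ASE measures (columns
    of ``values``) and song parameters (columns of ``song_params``),
    matched on the shared individual index."""
    common = values.index.intersection(song_params.index)
    rows = []
    for v in values.columns:
        for s in song_params.columns:
            r, p = correlate_phenotype(values.loc[common, v],
                                       song_params.loc[common, s])
            rows.append({"measure": v, "song_param": s, "r": r, "p": p,
                         "n": len(common)})
    return pd.DataFrame(rows)
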