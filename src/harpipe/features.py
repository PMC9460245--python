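"""Per-window feature extraction for inertial activity recognition.

Five feature families are computed per window and per channel, spanning the
time, frequency, wavelet and time-frequency domains:

* statistical descriptors (mean, sample standard deviation, median, mode,
  extrema) of the framed signal;
* empirical mode decomposition (EMD) with Hilbert-Huang descriptors —
  per-IMF energies and instantaneous-frequency moments;
* orthonormal Haar discrete wavelet transform energies;
* Shannon spectral entropy of the normalized one-sided power spectrum;
* wavelet packet decomposition with Shannon entropy of the leaf-node
  energy distribution.

EMD splits a signal into intrinsic mode functions (IMFs) c_a plus a residue
r_n with x = sum_a c_a + r_n holding exactly by construction; the Haar and
packet transforms use the orthonormal filter pair (1/sqrt(2), +-1/sqrt(2))
so that coefficient energy equals signal energy to rounding error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

logger = logging.getLogger(__name__)

__all__ = [
    "StatDescriptor",
    "EMDResult",
    "HaarDecomposition",
    "SpectralEntropyResult",
    "WaveletPacketTree",
    "FeatureMatrix",
    "FeatureConfig",
    "statistical_features",
    "emd",
    "hht_features",
    "haar_dwt",
    "haar_features",
    "spectral_entropy",
    "wavelet_packet_entropy",
    "extract_all",
    "build_feature_matrix",
    "minmax_fit_apply",
]


# ---------------------------------------------------------------------------
# statistical descriptors
# ---------------------------------------------------------------------------

@dataclass
class StatDescriptor:
    """Time-domain summary of one framed channel.

    ``mode`` is estimated for continuous data as the centre of the fullest of
    10 equal-width histogram bins spanning [minimum, maximum]; a constant
    input returns the constant itself.
    """

    n: int
    mean: float
    sample_std: float
    median: float
    mode: float
    minimum: float
    maximum: float

    def as_features(self) -> dict[str, float]:
        return {
            "stat_n": float(self.n),
            "stat_mean": self.mean,
            "stat_std": self.sample_std,
            "stat_median": self.median,
            "stat_mode": self.mode,
            "stat_min": self.minimum,
            "stat_max": self.maximum,
        }


def statistical_features(window_channel: np.ndarray) -> StatDescriptor:
    """Mean, sample std (n-1 denominator), median, histogram mode, min, max."""
    x = np.asarray(window_channel, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples for a sample standard deviation")
    mn, mx = float(x.min()), float(x.max())
    if mn == mx:
        mode = mn
    else:
        counts, edges = np.histogram(x, bins=10, range=(mn, mx))
        i = int(np.argmax(counts))  # first fullest bin on ties
        mode = float(0.5 * (edges[i] + edges[i + 1]))
    return StatDescriptor(
        n=n,
        mean=float(x.mean()),
        sample_std=float(x.std(ddof=1)),
        median=float(np.median(x)),
        mode=mode,
        minimum=mn,
        maximum=mx,
    )


# ---------------------------------------------------------------------------
# empirical mode decomposition / Hilbert-Huang features
# ---------------------------------------------------------------------------

@dataclass
class EMDResult:
    """IMFs and residue of an empirical mode decomposition.

    The elementwise identity ``source == sum(imfs) + residue`` holds exactly
    because the residue is computed by subtraction.
    """

    imfs: list[np.ndarray]
    residue: np.ndarray
    source: np.ndarray

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruction(self) -> np.ndarray:
        out = self.residue.copy()
        for c in self.imfs:
            out += c
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus collapse to one)."""
    d = np.diff(x)
    s = np.sign(d)
    # carry the last nonzero slope sign through plateaus
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    change = np.diff(s)
    maxima = np.flatnonzero(change < 0) + 1
    minima = np.flatnonzero(change > 0) + 1
    return maxima, minima


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, with extrema mirrored past both
    ends to suppress spline end swings."""
    n = x.size
    pos = idx.astype(float)
    val = x[idx]
    k = min(2, idx.size)
    left_pos = -pos[:k][::-1]
    left_val = val[:k][::-1]
    right_pos = 2.0 * (n - 1) - pos[-k:][::-1]
    right_val = val[-k:][::-1]
    pos = np.concatenate([left_pos, pos, right_pos])
    val = np.concatenate([left_val, val, right_val])
    # mirroring can duplicate endpoint abscissae; keep strictly increasing
    keep = np.concatenate([[True], np.diff(pos) > 0])
    spline = CubicSpline(pos[keep], val[keep])
    return spline(np.arange(n, dtype=float))


def _sift(x: np.ndarray, sd_stop: float, max_sift: int = 100) -> np.ndarray:
    """Extract one IMF by iterative envelope-mean subtraction.

    A sift candidate is accepted when the Cauchy criterion
    ``sum((prev - curr)**2) / sum(prev**2) < sd_stop`` is met.
    """
    h = x.copy()
    for _ in range(max_sift):
        maxima, minima = _local_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            break
        upper = _mirrored_envelope(h, maxima)
        lower = _mirrored_envelope(h, minima)
        m = 0.5 * (upper + lower)
        denom = float(np.sum(h * h))
        sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
        h = h - m
        if sd < sd_stop:
            break
    return h


def emd(signal: np.ndarray, max_imfs: int = 8, sd_stop: float = 0.2) -> EMDResult:
    """Empirical mode decomposition by cubic-spline sifting.

    Envelopes are cubic splines through the local maxima/minima with
    mirrored boundary extrema; sifting of one IMF stops at the Cauchy
    criterion ``sd_stop``, and decomposition stops after ``max_imfs`` IMFs or
    when the residue has fewer than 3 extrema.

    Parameters
    ----------
    signal : array of length >= 16
    max_imfs : int
        Upper bound on the number of extracted IMFs.
    sd_stop : float
        Cauchy sifting threshold (standard value 0.2).
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 16:
        raise ValueError("EMD needs at least 16 samples")
    if not np.isfinite(x).all():
        raise ValueError("EMD input must be finite")
    imfs: list[np.ndarray] = []
    residue = x.copy()
    while len(imfs) < max_imfs:
        maxima, minima = _local_extrema(residue)
        if maxima.size + minima.size < 3:
            break
        imf = _sift(residue, sd_stop)
        imfs.append(imf)
        residue = residue - imf
    # exact reconstruction: recompute the residue by subtraction from source
    residue = x - np.sum(imfs, axis=0) if imfs else x.copy()
    return EMDResult(imfs=imfs, residue=residue, source=x)


def _instantaneous_frequency(c: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Instantaneous frequency (Hz) from the analytic-signal phase derivative."""
    analytic = hilbert(c)
    phase = np.unwrap(np.angle(analytic))
    return np.diff(phase) * sample_rate_hz / (2.0 * np.pi)


def hht_features(
    decomp: EMDResult, sample_rate_hz: float, n_keep: int = 3
) -> dict[str, float]:
    """Hilbert-Huang descriptors of the first ``n_keep`` IMFs.

    For each kept IMF: energy, fraction of total signal energy, and the mean
    and standard deviation of the instantaneous frequency over interior
    samples (5% trimmed at each end, where the discrete Hilbert transform is
    unreliable).  Families for missing IMFs are zero-filled so the feature
    vector always has length ``4 * n_keep``.
    """
    total = float(np.sum(decomp.source**2))
    out: dict[str, float] = {}
    for i in range(n_keep):
        prefix = f"hht_imf{i + 1}"
        if i < decomp.n_imfs:
            c = decomp.imfs[i]
            energy = float(np.sum(c * c))
            frac = energy / total if total > 0 else 0.0
            if energy > 0:
                inst = _instantaneous_frequency(c, sample_rate_hz)
                k = max(1, inst.size // 20)
                interior = inst[k:-k] if inst.size > 2 * k else inst
                if_mean = float(interior.mean())
                if_std = float(interior.std())
            else:
                if_mean = if_std = 0.0
            out[f"{prefix}_energy"] = energy
            out[f"{prefix}_energy_frac"] = frac
            out[f"{prefix}_if_mean"] = if_mean
            out[f"{prefix}_if_std"] = if_std
        else:
            out[f"{prefix}_energy"] = 0.0
            out[f"{prefix}_energy_frac"] = 0.0
            out[f"{prefix}_if_mean"] = 0.0
            out[f"{prefix}_if_std"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Haar wavelet transform
# ---------------------------------------------------------------------------

#: The Haar mother wavelet: +1 on [0, 1/2), -1 on [1/2, 1), 0 elsewhere.
def haar_mother(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where((t >= 0) & (t < 0.5), 1.0, np.where((t >= 0.5) & (t < 1.0), -1.0, 0.0))


@dataclass
class HaarDecomposition:
    """Multi-level orthonormal Haar DWT.

    ``approximations[k]`` and ``details[k]`` hold the level-(k+1)
    coefficients, each of length n / 2^(k+1); under the orthonormal
    convention a_k = (x_2k + x_2k+1)/sqrt(2), d_k = (x_2k - x_2k+1)/sqrt(2)
    total coefficient energy equals input energy.
    """

    levels: int
    approximations: list[np.ndarray]
    details: list[np.ndarray]

    def coefficient_energy(self) -> float:
        e = float(np.sum(self.approximations[-1] ** 2))
        for d in self.details:
            e += float(np.sum(d * d))
        return e


def haar_dwt(signal: np.ndarray, levels: int = 3) -> HaarDecomposition:
    """Orthonormal Haar discrete wavelet transform.

    If the length is not a multiple of ``2**levels`` the tail is truncated to
    the largest such multiple before transforming.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if levels < 1:
        raise ValueError("levels must be >= 1")
    block = 2**levels
    if x.size < block:
        raise ValueError(f"need at least {block} samples for {levels} levels")
    x = x[: (x.size // block) * block]
    approximations, details = [], []
    current = x
    for _ in range(levels):
        a, d = pywt.dwt(current, "haar", mode="periodization")
        approximations.append(a)
        details.append(d)
        current = a
    return HaarDecomposition(levels=levels, approximations=approximations, details=details)


def haar_features(decomp: HaarDecomposition) -> dict[str, float]:
    """Energy and spread of each detail band plus the final approximation.

    Per level: detail energy (sum of squared coefficients, estimating band
    power) and detail standard deviation; plus the final approximation's
    energy and mean.
    """
    out: dict[str, float] = {}
    for i, d in enumerate(decomp.details, start=1):
        out[f"haar_d{i}_energy"] = float(np.sum(d * d))
        out[f"haar_d{i}_std"] = float(d.std())
    a = decomp.approximations[-1]
    out["haar_a_energy"] = float(np.sum(a * a))
    out["haar_a_mean"] = float(a.mean())
    return out


# ---------------------------------------------------------------------------
# spectral entropy
# ---------------------------------------------------------------------------

@dataclass
class SpectralEntropyResult:
    """Shannon entropy of the normalized one-sided power spectrum.

    ``power`` excludes the DC bin; ``normalized_power`` Q sums to one;
    ``shannon_terms`` are Q*log(1/Q) in nats with 0*log(1/0) = 0; and
    ``normalized_entropy`` divides by log(n_bins) so a flat spectrum scores 1
    and a single-bin tone scores 0.
    """

    power: np.ndarray
    normalized_power: np.ndarray
    shannon_terms: np.ndarray
    entropy: float
    normalized_entropy: float
    n_bins: int
    frequencies_hz: np.ndarray


def spectral_entropy(signal: np.ndarray, sample_rate_hz: float) -> SpectralEntropyResult:
    """Normalized Shannon spectral entropy of a real signal (natural log)."""
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    spectrum = np.fft.rfft(x)
    power = np.abs(spectrum[1:]) ** 2  # one-sided, DC excluded
    total = float(power.sum())
    if total <= 0.0:
        raise ValueError("spectrum of an all-constant signal cannot be normalized")
    q = power / total
    terms = np.where(q > 0, q * np.log(np.divide(1.0, q, where=q > 0, out=np.ones_like(q))), 0.0)
    entropy = float(terms.sum())
    n_bins = power.size
    return SpectralEntropyResult(
        power=power,
        normalized_power=q,
        shannon_terms=terms,
        entropy=entropy,
        normalized_entropy=entropy / np.log(n_bins),
        n_bins=n_bins,
        frequencies_hz=np.fft.rfftfreq(x.size, d=1.0 / sample_rate_hz)[1:],
    )


# ---------------------------------------------------------------------------
# wavelet packet entropy
# ---------------------------------------------------------------------------

@dataclass
class WaveletPacketTree:
    """Full Haar wavelet packet tree with per-node energies.

    ``nodes`` maps (level i, position j) with j in 1..2^i to the coefficient
    sequence of that node; both low- and high-pass branches are recursed, so
    the leaves tile the frequency axis uniformly.  ``packet_entropy`` is the
    Shannon entropy (nats) of the normalized leaf-energy distribution.
    """

    levels: int
    nodes: dict[tuple[int, int], np.ndarray]
    lowpass: np.ndarray
    highpass: np.ndarray
    node_energies: dict[tuple[int, int], float]
    packet_entropy: float

    def leaf_energies(self) -> np.ndarray:
        return np.array(
            [self.node_energies[(self.levels, j)] for j in range(1, 2**self.levels + 1)]
        )


def wavelet_packet_entropy(signal: np.ndarray, levels: int = 2) -> WaveletPacketTree:
    """Haar wavelet packet decomposition and leaf-energy Shannon entropy."""
    x = np.asarray(signal, dtype=float).ravel()
    if levels < 1:
        raise ValueError("levels must be >= 1")
    block = 2**levels
    if x.size < block:
        raise ValueError(f"need at least {block} samples for {levels} levels")
    x = x[: (x.size // block) * block]
    wp = pywt.WaveletPacket(data=x, wavelet="haar", mode="periodization", maxlevel=levels)
    nodes: dict[tuple[int, int], np.ndarray] = {}
    energies: dict[tuple[int, int], float] = {}
    for i in range(1, levels + 1):
        for j, node in enumerate(wp.get_level(i, order="natural"), start=1):
            data = np.asarray(node.data, dtype=float)
            nodes[(i, j)] = data
            energies[(i, j)] = float(np.sum(data * data))
    leaf = np.array([energies[(levels, j)] for j in range(1, block + 1)])
    total = float(leaf.sum())
    if total > 0:
        q = leaf / total
        packet_entropy = float(-np.sum(q[q > 0] * np.log(q[q > 0])))
    else:
        packet_entropy = 0.0
    wavelet = pywt.Wavelet("haar")
    return WaveletPacketTree(
        levels=levels,
        nodes=nodes,
        lowpass=np.asarray(wavelet.dec_lo),
        highpass=np.asarray(wavelet.dec_hi),
        node_energies=energies,
        packet_entropy=packet_entropy,
    )


def wpe_features(tree: WaveletPacketTree) -> dict[str, float]:
    """Normalized leaf energies plus the packet entropy."""
    leaf = tree.leaf_energies()
    total = float(leaf.sum())
    q = leaf / total if total > 0 else np.zeros_like(leaf)
    out = {f"wpe_leaf{j + 1}_energy_frac": float(q[j]) for j in range(leaf.size)}
    out["wpe_entropy"] = tree.packet_entropy
    return out


# ---------------------------------------------------------------------------
# composition and normalization
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    """Tunables of the per-window feature pool.

    n_keep : IMFs retained for Hilbert-Huang descriptors (zero-filled when
        the decomposition is shorter).
    haar_levels : depth of the Haar DWT.
    wpe_levels : depth of the wavelet packet tree.
    emd_max_imfs, emd_sd_stop : EMD stopping controls.
    """

    n_keep: int = 3
    haar_levels: int = 3
    wpe_levels: int = 2
    emd_max_imfs: int = 8
    emd_sd_stop: float = 0.2

    def features_per_channel(self) -> int:
        return 7 + 4 * self.n_keep + (2 * self.haar_levels + 2) + 2 + (2**self.wpe_levels + 1)


def _channel_features(
    x: np.ndarray, sample_rate_hz: float, config: FeatureConfig
) -> dict[str, float]:
    out: dict[str, float] = {}
    try:
        out.update(statistical_features(x).as_features())
        decomp = emd(x, max_imfs=config.emd_max_imfs, sd_stop=config.emd_sd_stop)
        out.update(hht_features(decomp, sample_rate_hz, n_keep=config.n_keep))
        out.update(haar_features(haar_dwt(x, levels=config.haar_levels)))
        try:
            se = spectral_entropy(x, sample_rate_hz)
            out["se_entropy"] = se.entropy
            out["se_normalized"] = se.normalized_entropy
        except ValueError:
            # constant window: no oscillatory power to normalize
            out["se_entropy"] = 0.0
            out["se_normalized"] = 0.0
        out.update(wpe_features(wavelet_packet_entropy(x, levels=config.wpe_levels)))
    except ValueError as err:
        raise ValueError(f"feature extraction failed: {err}") from err
    return out


def extract_all(window, config: FeatureConfig | None = None) -> tuple[list[str], np.ndarray]:
    """All feature families for every channel of one window.

    Returns (names, values) with names of the form ``ch<j>|<family feature>``,
    deterministic and stable across calls.
    """
    config = config or FeatureConfig()
    names: list[str] = []
    values: list[float] = []
    for j in range(window.n_channels):
        feats = _channel_features(window.samples[:, j], window.sample_rate_hz, config)
        for key, val in feats.items():
            names.append(f"ch{j}|{key}")
            values.append(val)
    return names, np.asarray(values, dtype=float)


@dataclass
class FeatureMatrix:
    """Named feature vectors per window with subject/label metadata."""

    feature_names: list[str]
    values: np.ndarray
    subject_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("values must be (windows, features) matching feature_names")
        if len(self.subject_ids) != self.values.shape[0] or len(self.labels) != self.values.shape[0]:
            raise ValueError("metadata length must match row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take(self, indices: np.ndarray) -> "FeatureMatrix":
        """Row subset preserving order and metadata."""
        idx = np.asarray(indices)
        return FeatureMatrix(
            feature_names=list(self.feature_names),
            values=self.values[idx],
            subject_ids=self.subject_ids[idx],
            labels=self.labels[idx],
        )

    def select_columns(self, names: list[str]) -> "FeatureMatrix":
        """Column subset (in this matrix's column order) preserving metadata."""
        wanted = set(names)
        keep = [i for i, nm in enumerate(self.feature_names) if nm in wanted]
        missing = wanted - {self.feature_names[i] for i in keep}
        if missing:
            raise ValueError(f"unknown feature names: {sorted(missing)}")
        return FeatureMatrix(
            feature_names=[self.feature_names[i] for i in keep],
            values=self.values[:, keep],
            subject_ids=self.subject_ids,
            labels=self.labels,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        return df

    def to_csv(self, path) -> None:
        # %.17g keeps doubles bit-exact through a text round trip
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        meta = ["subject_id", "label"]
        names = [c for c in df.columns if c not in meta]
        return cls(
            feature_names=names,
            values=df[names].to_numpy(dtype=float),
            subject_ids=df["subject_id"].astype(str).to_numpy(),
            labels=df["label"].astype(str).to_numpy(),
        )


def build_feature_matrix(windows, config: FeatureConfig | None = None) -> FeatureMatrix:
    """Extract features for every window into one named matrix."""
    config = config or FeatureConfig()
    if not windows:
        raise ValueError("no windows to extract features from")
    names0, row0 = extract_all(windows[0], config)
    mat = np.empty((len(windows), len(names0)))
    mat[0] = row0
    for i, win in enumerate(windows[1:], start=1):
        names, row = extract_all(win, config)
        if names != names0:
            raise ValueError("inconsistent feature names across windows")
        mat[i] = row
    return FeatureMatrix(
        feature_names=names0,
        values=mat,
        subject_ids=np.array([w.subject_id for w in windows]),
        labels=np.array([w.label for w in windows]),
    )


def minmax_fit_apply(
    train: FeatureMatrix, others: list[FeatureMatrix] | None = None
) -> tuple[FeatureMatrix, list[FeatureMatrix], np.ndarray, np.ndarray]:
    """Min-max normalize to [0, 1] using training-set extremes only.

    Constant training columns map to 0.5 everywhere; values of the other
    matrices are clipped to [0, 1] after the affine map, so no statistic of a
    test fold ever influences the scaling.
    """
    others = others or []
    for om in others:
        if om.feature_names != train.feature_names:
            raise ValueError("feature-name mismatch between matrices")
    if train.n_rows == 0:
        raise ValueError("training matrix is empty")
    mins = train.values.min(axis=0)
    maxs = train.values.max(axis=0)
    span = maxs - mins
    constant = span == 0

    def _apply(fm: FeatureMatrix, clip: bool) -> FeatureMatrix:
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = (fm.values - mins) / np.where(constant, 1.0, span)
        scaled[:, constant] = 0.5
        if clip:
            scaled = np.clip(scaled, 0.0, 1.0)
        return FeatureMatrix(
            feature_names=list(fm.feature_names),
            values=scaled,
            subject_ids=fm.subject_ids,
            labels=fm.labels,
        )

    return _apply(train, clip=False), [_apply(om, clip=True) for om in others], mins, maxs
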