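"""Band-wise magnitude-squared coherence between scalp EEG channels.

The estimator follows the classical averaged-cross-spectrum construction:
the record is cut into sliding tapered windows; per window w and channel x
the discrete Fourier transform yields cosine/sine coefficients
``a_x(f), b_x(f)`` (for channel y written ``u_y, v_y``); coherence at f is

    Coh(f) = [ (sum_N (a_x u_y + b_x v_y))^2 + (sum_N (a_x v_y - b_x u_y))^2 ]
             / [ sum_N (a_x^2 + b_x^2) * sum_N (u_y^2 + v_y^2) ]

i.e. ``|sum_N X conj(Y)|^2 / (sum_N |X|^2 * sum_N |Y|^2)`` with
``X = a + i b``.  Band adjacency matrices average per-bin coherence over the
six conventional bands (delta 1-4, theta 4-8, alpha 8-12, beta 12-25,
high-beta 25-30, gamma 30-40 Hz), giving one 19 x 19 symmetric weighted
matrix per band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

__all__ = [
    "CHANNELS_1020",
    "BANDS",
    "EEGRecording",
    "SpectralCoefficients",
    "CoherenceMatrixSet",
    "reject_artifacts",
    "windowed_spectra",
    "coherence",
    "band_adjacency",
]

#: The 19 scalp channels of the international 10-20 montage, in the
#: conventional anterior-to-posterior order.
CHANNELS_1020 = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: (name, low Hz, high Hz); intervals are half-open [low, high) except the
#: gamma band which is closed at 40 Hz, so shared edges are never counted
#: twice.
BANDS = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 25.0),
    ("high_beta", 25.0, 30.0),
    ("gamma", 30.0, 40.0),
)

#: Modern temporal/posterior-temporal labels mapped onto the older 10-20
#: nomenclature used here.
CHANNEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


def normalize_channel_label(label: str) -> str:
    """Map a channel label to canonical 10-20 form (T7 -> T3 etc.)."""
    lab = label.strip()
    up = lab.upper()
    canon = {c.upper(): c for c in CHANNELS_1020}
    up = CHANNEL_ALIASES.get(up, up)
    return canon.get(up, lab)


@dataclass
class EEGRecording:
    """A multichannel scalp recording with named channels.

    ``data`` has shape ``(n_channels, n_samples)``; ``bad_samples`` marks
    samples excluded from spectral averaging (set by artifact rejection).
    """

    data: np.ndarray
    fs: float
    channels: tuple = CHANNELS_1020
    reference: str = "linked-ears"
    bad_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count does not match labels")
        if self.fs <= 80:
            raise ValueError("fs must exceed 80 Hz (2 x top gamma edge)")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class SpectralCoefficients:
    """Per-window Fourier coefficients for every channel.

    ``coeffs`` is complex with shape ``(n_windows, n_channels, n_freqs)``;
    the real part holds the cosine coefficients, the negated imaginary part
    the sine coefficients.  ``freqs`` is the frequency grid with spacing
    ``1 / window_s``.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    channels: tuple
    window_s: float
    overlap: float
    taper: str = "hann"

    @property
    def n_windows(self) -> int:
        return self.coeffs.shape[0]

    def channel_index(self, label: str) -> int:
        lab = normalize_channel_label(label)
        try:
            return self.channels.index(lab)
        except ValueError as exc:
            raise KeyError(f"unknown channel {label!r}") from exc


@dataclass
class CoherenceMatrixSet:
    """Per-band symmetric coherence matrices with unit diagonal."""

    matrices: dict  # band name -> (n, n) ndarray, diagonal 1
    channels: tuple
    bands: tuple = BANDS

    def graph_matrix(self, band: str) -> np.ndarray:
        """The band matrix with the diagonal forced to zero, for graph use."""
        m = self.matrices[band].copy()
        np.fill_diagonal(m, 0.0)
        return m


def reject_artifacts(
    rec: EEGRecording, amp_threshold: float, window_s: float = 2.0
) -> EEGRecording:
    """Mask segments in which any channel exceeds ``amp_threshold``.

    The record is scanned in consecutive non-overlapping windows of
    ``window_s``; offending windows are marked bad and later excluded from
    spectral averaging.  Raises if fewer than 8 clean windows remain.
    """
    if amp_threshold <= 0:
        raise ValueError("threshold must be positive")
    n = rec.data.shape[1]
    step = int(round(window_s * rec.fs))
    bad = np.zeros(n, dtype=bool)
    n_clean = 0
    for start in range(0, n - step + 1, step):
        seg = rec.data[:, start : start + step]
        if np.any(np.abs(seg) > amp_threshold):
            bad[start : start + step] = True
        else:
            n_clean += 1
    if n_clean < 8:
        raise ValueError("insufficient clean data: fewer than 8 artifact-free windows")
    return EEGRecording(
        data=rec.data,
        fs=rec.fs,
        channels=rec.channels,
        reference=rec.reference,
        bad_samples=bad,
    )


def windowed_spectra(
    rec: EEGRecording,
    window_s: float = 2.0,
    overlap: float = 0.75,
    taper: str = "hann",
    max_freq: float | None = None,
) -> SpectralCoefficients:
    """Sliding-window tapered Fourier coefficients for all channels.

    A 2 s window gives 0.5 Hz resolution, enough to resolve the 1 Hz delta
    edge.  Windows overlapping samples flagged bad by artifact rejection are
    dropped.  ``max_freq`` truncates the stored grid (the coherence bands
    only need <= 40 Hz); ``None`` keeps the full grid to Nyquist.
    """
    if not 0.0 <= overlap <= 0.95:
        raise ValueError("overlap must lie in [0, 0.95]")
    if window_s < 2.0:
        raise ValueError("window_s must be >= 2 s to resolve the 1 Hz delta edge")
    nper = int(round(window_s * rec.fs))
    n = rec.data.shape[1]
    if n < nper:
        raise ValueError("record shorter than one window")
    step = max(1, int(round(nper * (1.0 - overlap))))
    starts = np.arange(0, n - nper + 1, step)
    if rec.bad_samples is not None:
        keep = [s for s in starts if not rec.bad_samples[s : s + nper].any()]
        starts = np.asarray(keep, dtype=int)
    if len(starts) < 8:
        raise ValueError("insufficient clean data: fewer than 8 usable windows")
    win = get_window(taper, nper, fftbins=True)
    freqs = np.fft.rfftfreq(nper, d=1.0 / rec.fs)
    if max_freq is not None:
        fmask = freqs <= max_freq
    else:
        fmask = np.ones_like(freqs, dtype=bool)
    coeffs = np.empty(
        (len(starts), rec.data.shape[0], int(fmask.sum())), dtype=complex
    )
    for k, s in enumerate(starts):
        coeffs[k] = np.fft.rfft(rec.data[:, s : s + nper] * win, axis=1)[:, fmask]
    return SpectralCoefficients(
        coeffs=coeffs,
        freqs=freqs[fmask],
        channels=tuple(rec.channels),
        window_s=window_s,
        overlap=overlap,
        taper=taper,
    )


def _cross_sums(spec: SpectralCoefficients) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated cross-spectral sums S[x, y, f] = sum_w X conj(Y) and the
    auto sums P[x, f] = sum_w |X|^2."""
    c = spec.coeffs
    S = np.einsum("wxf,wyf->xyf", c, np.conj(c), optimize=True)
    P = np.real(np.einsum("wxf,wxf->xf", c, np.conj(c)))
    return S, P


def coherence(
    spec: SpectralCoefficients, x: str | int, y: str | int, f: float
) -> float:
    """Magnitude-squared coherence between channels x and y at frequency f.

    f must lie on the window frequency grid.  Symmetric in (x, y), invariant
    to per-channel rescaling, exactly 1 for x = y.  Zero power in either
    channel at f yields 0 with a warning.
    """
    if spec.n_windows < 8:
        raise ValueError("need at least 8 windows for a stable estimate")
    fi = int(np.argmin(np.abs(spec.freqs - f)))
    if abs(spec.freqs[fi] - f) > 1e-9:
        raise ValueError(f"frequency {f} Hz is not on the grid")
    ix = spec.channel_index(x) if isinstance(x, str) else int(x)
    iy = spec.channel_index(y) if isinstance(y, str) else int(y)
    if iy < ix:  # |cross|^2 is conjugation-invariant: order canonically
        ix, iy = iy, ix
    X = spec.coeffs[:, ix, fi]
    Y = spec.coeffs[:, iy, fi]
    px = float(np.sum(np.abs(X) ** 2))
    py = float(np.sum(np.abs(Y) ** 2))
    if px == 0.0 or py == 0.0:
        warnings.warn("zero power at requested frequency; coherence set to 0")
        return 0.0
    if ix == iy:
        return 1.0
    cross = np.sum(X * np.conj(Y))
    return float(min(np.abs(cross) ** 2 / (px * py), 1.0))


def band_adjacency(
    spec: SpectralCoefficients, bands: tuple = BANDS
) -> CoherenceMatrixSet:
    """Per-band 19 x 19 coherence adjacency matrices.

    Entry (i, j) is the mean per-bin coherence over the band's frequency
    bins ([low, high) except the last band, closed at its upper edge).  A
    single symmetrised pass guarantees exact symmetry; the stored diagonal
    is 1 (self-coherence), with :meth:`CoherenceMatrixSet.graph_matrix`
    providing the zero-diagonal version used for graph metrics.
    """
    if spec.n_windows < 8:
        raise ValueError("need at least 8 windows")
    S, P = _cross_sums(spec)
    denom = P[:, None, :] * P[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(S) ** 2 / denom
    coh = np.where(denom > 0, coh, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    # enforce exact symmetry (S is Hermitian so this is a numerical no-op)
    coh = 0.5 * (coh + np.swapaxes(coh, 0, 1))
    top_edge = max(high for _, _, high in bands)
    matrices = {}
    for name, low, high in bands:
        closed = high == top_edge
        if closed:
            mask = (spec.freqs >= low) & (spec.freqs <= high)
        else:
            mask = (spec.freqs >= low) & (spec.freqs < high)
        if not mask.any():
            raise ValueError(f"band {name} contains no frequency bins on this grid")
        m = coh[:, :, mask].mean(axis=2)
        np.fill_diagonal(m, 1.0)
        matrices[name] = m
    return CoherenceMatrixSet(matrices=matrices, channels=spec.channels, bands=bands)
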