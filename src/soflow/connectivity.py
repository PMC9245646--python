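"""Sliding-window MVAR modelling and generalized partial directed coherence.

Directed (Granger-type) information flow between EEG channels is estimated
by fitting a multivariate autoregressive (MVAR) model

    X(n) = sum_{k=1..p} A_k X(n-k) + w(n),    w ~ N(0, Sigma)

in short windows, moving the coefficients to the frequency domain,

    Abar_ij(f) = delta_ij - sum_k a_ij(k) exp(-2 pi i f k),

and normalizing columns with the residual variances to obtain the
generalized partial directed coherence (GPDC)

    |pi_ij(f)| = (1/s_i) |Abar_ij(f)| / sqrt( sum_k |Abar_kj(f)|^2 / s_k^2 ),

with s_i = sqrt(Sigma_ii). The j-th column is the outflow profile of
channel j and satisfies sum_i |pi_ij(f)|^2 = 1 at every frequency, so the
noise-variance weighting makes the measure insensitive to per-channel
amplitude scale.

Two coefficient estimators are provided. Ordinary least squares
(``method="ols"``) is used whenever the window supplies more equations
than regressors. The Vieira-Morf multichannel Burg recursion
(``method="vm"``) estimates the coefficients through order-recursive
reflection matrices and stays well defined on short windows (e.g. a
0.5-s, 128-sample window with 12 channels and order 13, where least
squares would be underdetermined); it is the default for the sliding-window
stage.

Two scalar flow quantifiers summarize a frequency-averaged GPDC matrix
``pi(i, j)`` for a source channel CH:

    CH->R      = sum_{i in R} pi(i, CH)^2           (flow into region R)
    CHoutflow  = sum over regions R != region(CH) of CH->R
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .channels import ANALYSIS_CHANNELS, DEFAULT_SCHEME, RegionScheme, SOURCE_CHANNELS

logger = logging.getLogger(__name__)

#: Sliding-window geometry: 0.5-s window, 2-sample stride at 256 Hz.
WINDOW_S = 0.5
STRIDE_SAMPLES = 2
EPOCH_HALF_S = 1.0
DEFAULT_ORDER = 13


class MVARStabilityError(ValueError):
    """Raised when VAR coefficients define an unstable process."""


@dataclass
class MVARModel:
    """Fitted MVAR model: coefficients ``A[k-1][i, j]`` and noise covariance."""

    order: int
    coeffs: np.ndarray  # (p, N, N)
    sigma: np.ndarray   # (N, N) residual covariance
    n_obs: int

    def __post_init__(self) -> None:
        p, n, m = self.coeffs.shape
        if n != m or p != self.order:
            raise ValueError("coefficient array must be (order, N, N)")
        if self.sigma.shape != (n, n):
            raise ValueError("sigma must be N x N")
        if np.any(np.diag(self.sigma) <= 0):
            raise ValueError("sigma diagonal must be strictly positive")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of stacked (p, N, N) VAR coefficients."""
    p, n, _ = coeffs.shape
    top = np.concatenate(list(coeffs), axis=1)
    bottom = np.eye(n * (p - 1), n * p) if p > 1 else np.empty((0, n))
    return np.vstack([top, bottom]) if p > 1 else top


def spectral_radius(coeffs: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs)))))


def stationary_covariance(coeffs: np.ndarray, noise_cov: np.ndarray) -> np.ndarray:
    """Closed-form stationary covariance via the discrete Lyapunov equation.

    Solves ``P = F P F' + Q`` for the companion form F and returns the
    upper-left N x N block (the lag-0 covariance of the process).
    """
    p, n, _ = coeffs.shape
    f = companion_matrix(coeffs)
    q = np.zeros_like(f)
    q[:n, :n] = noise_cov
    big = scipy.linalg.solve_discrete_lyapunov(f, q)
    return big[:n, :n]


def _lagged_design(window: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    n, w = window.shape
    y = window[:, p:]                               # (N, W-p)
    z = np.empty((n * p, w - p))
    for k in range(1, p + 1):
        z[(k - 1) * n : k * n] = window[:, p - k : w - k]
    return y, z


def fit_mvar(window: np.ndarray, p: int, method: str = "ols") -> MVARModel:
    """Fit an MVAR(p) model to a channels x samples window.

    The window is demeaned per channel before fitting. ``method="ols"``
    solves the stacked least-squares problem and requires
    ``W - p > N * p``; ``method="vm"`` runs the Vieira-Morf recursion and
    only needs ``W > 2 p + 1``.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError("window must be channels x samples")
    n, w = window.shape
    if p < 1:
        raise ValueError("model order must be >= 1")
    window = window - window.mean(axis=1, keepdims=True)
    if method == "vm":
        return _fit_vieira_morf(window, p)
    if method != "ols":
        raise ValueError(f"unknown MVAR method {method!r}")
    if w - p <= n * p:
        raise ValueError(
            f"insufficient equations for OLS: {w - p} <= {n * p} "
            f"(W={w}, p={p}, N={n}); lower p or use method='vm'"
        )
    y, z = _lagged_design(window, p)
    gram = z @ z.T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"singular regressor Gram matrix (cond={cond:.2e}); try a lower order p"
        )
    beta = np.linalg.solve(gram, z @ y.T).T            # (N, N*p)
    resid = y - beta @ z
    sigma = resid @ resid.T / (w - p)
    coeffs = beta.reshape(n, p, n).transpose(1, 0, 2)
    return MVARModel(order=p, coeffs=coeffs, sigma=sigma, n_obs=w - p)


def _fit_vieira_morf(x: np.ndarray, p: int) -> MVARModel:
    """Vieira-Morf (multichannel Burg) order-recursive MVAR estimator."""
    n, w = x.shape
    if w <= 2 * p + 1:
        raise ValueError(f"window too short for order {p}: {w} samples")
    ef = x.copy()
    eb = x.copy()
    a = np.zeros((p, n, n))  # forward coefficients of current order
    b = np.zeros((p, n, n))  # backward coefficients
    for m in range(1, p + 1):
        efm = ef[:, m:]
        ebm = eb[:, m - 1 : -1]
        rff = efm @ efm.T
        rbb = ebm @ ebm.T
        rfb = efm @ ebm.T
        try:
            sf = np.linalg.cholesky(rff)
            sb = np.linalg.cholesky(rbb)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"degenerate prediction-error covariance at stage {m}"
            ) from exc
        rho = scipy.linalg.solve_triangular(sf, rfb, lower=True)
        rho = scipy.linalg.solve_triangular(sb, rho.T, lower=True).T
        arf = sf @ rho @ np.linalg.inv(sb)
        arb = sb @ rho.T @ np.linalg.inv(sf)
        a_prev = a[: m - 1].copy()
        b_prev = b[: m - 1].copy()
        for k in range(m - 1):
            a[k] = a_prev[k] - arf @ b_prev[m - 2 - k]
            b[k] = b_prev[k] - arb @ a_prev[m - 2 - k]
        a[m - 1] = arf
        b[m - 1] = arb
        ef_new = ef[:, 1:] - arf @ eb[:, :-1]
        eb_new = eb[:, :-1] - arb @ ef[:, 1:]
        ef = ef_new
        eb = eb_new
    resid = ef[:, p - 1 :] if ef.shape[1] > p else ef
    sigma = resid @ resid.T / max(resid.shape[1], 1)
    sigma = 0.5 * (sigma + sigma.T)
    if np.any(np.diag(sigma) <= 0):
        raise ValueError("Vieira-Morf produced a degenerate residual covariance")
    return MVARModel(order=p, coeffs=a, sigma=sigma, n_obs=w - p)


def select_order_aic(
    windows: list[np.ndarray] | np.ndarray,
    p_max: int,
    method: str = "ols",
) -> int:
    """Select one global MVAR order by the median AIC across sample windows.

    AIC(p) = ln det Sigma_hat(p) + 2 p N^2 / W per window; the returned
    order minimizes the median over windows, mirroring the use of a single
    order for every window of the analysis.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if isinstance(windows, np.ndarray) and windows.ndim == 2:
        windows = [windows]
    aic = np.full((len(windows), p_max), np.nan)
    for i, win in enumerate(windows):
        n, w = np.asarray(win).shape
        for p in range(1, p_max + 1):
            try:
                model = fit_mvar(win, p, method=method)
            except ValueError:
                continue
            sign, logdet = np.linalg.slogdet(model.sigma)
            if sign <= 0:
                continue
            aic[i, p - 1] = logdet + 2 * p * n * n / w
    med = np.nanmedian(aic, axis=0)
    if np.all(np.isnan(med)):
        raise ValueError("no MVAR order could be fitted on any window")
    return int(np.nanargmin(med)) + 1


def default_freq_grid(n_bins: int = 128) -> np.ndarray:
    """Normalized frequency grid: n_bins uniform points on (0, 0.5].

    At fs = 256 Hz the default 128 bins sit at 1, 2, ..., 128 Hz.
    """
    return np.arange(1, n_bins + 1) / (2.0 * n_bins)


@dataclass
class GPDCResult:
    """Frequency-resolved and frequency-averaged GPDC matrices."""

    pi_f: np.ndarray       # (n_freq, N, N) nonnegative |pi_ij(f)|
    pi_avg: np.ndarray     # (N, N) frequency-averaged matrix
    freqs: np.ndarray
    window_center: float | None = None  # seconds (relative to trough for SO windows)


def spectral_transfer(coeffs: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Abar(f) = I - sum_k A_k exp(-2 pi i f k) for each normalized f."""
    p, n, _ = coeffs.shape
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k))      # (n_freq, p)
    af = -np.tensordot(phase, coeffs, axes=(1, 0))        # (n_freq, N, N)
    af[:, np.arange(n), np.arange(n)] += 1.0
    return af


def gpdc(
    model: MVARModel,
    freqs: np.ndarray | None = None,
    average: str = "magnitude",
    window_center: float | None = None,
) -> GPDCResult:
    """Generalized partial directed coherence of a fitted MVAR model.

    ``average`` controls the frequency reduction feeding the quantifiers:
    ``"magnitude"`` averages |pi_ij(f)| (default), ``"power"`` averages
    |pi_ij(f)|^2 and square-roots the result so both modes return a matrix
    on the magnitude scale.
    """
    if freqs is None:
        freqs = default_freq_grid()
    sdiag = np.diag(model.sigma)
    if np.any(sdiag <= 0):
        raise ValueError("noise covariance has non-positive diagonal")
    af = spectral_transfer(model.coeffs, freqs)
    w = 1.0 / sdiag  # 1 / Sigma_ii = 1 / sigma_ii^2
    num = np.abs(af) * np.sqrt(w)[None, :, None]
    denom = np.sqrt(np.einsum("fkj,k->fj", np.abs(af) ** 2, w))
    pi_f = num / denom[:, None, :]
    if average == "magnitude":
        pi_avg = pi_f.mean(axis=0)
    elif average == "power":
        pi_avg = np.sqrt((pi_f**2).mean(axis=0))
    else:
        raise ValueError(f"unknown frequency-average mode {average!r}")
    return GPDCResult(pi_f=pi_f, pi_avg=pi_avg, freqs=np.asarray(freqs),
                      window_center=window_center)


def quantifiers(
    pi_avg: np.ndarray,
    source: str,
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> tuple[float, dict[str, float]]:
    """Flow quantifiers (CHoutflow, CH->R per region) from a 12x12 pi matrix.

    CH->R sums squared flow entries into region R's channels; CHoutflow
    sums CH->R over the three regions other than the source's own.
    """
    if pi_avg.shape != (len(ANALYSIS_CHANNELS),) * 2:
        raise ValueError("pi_avg must be 12 x 12 in the fixed channel order")
    source = source.strip()
    if source not in ANALYSIS_CHANNELS:
        raise KeyError(f"unknown source channel {source!r}")
    j = ANALYSIS_CHANNELS.index(source)
    own = scheme.region_of(source)
    to_region: dict[str, float] = {}
    for region in scheme.regions:
        rows = scheme.channel_indices(region)
        to_region[region] = float(np.sum(pi_avg[rows, j] ** 2))
    outflow = float(sum(v for r, v in to_region.items() if r != own))
    return outflow, to_region


@dataclass
class QuantifierSeries:
    """Per-SO flow quantifier time series for one source channel.

    193 values at window centers from -750 ms to +750 ms around the SO
    trough (0.5-s window, 2-sample stride at 256 Hz).
    """

    so_id: int
    source: str
    window_centers: np.ndarray            # seconds relative to trough
    outflow: np.ndarray                   # (n_windows,)
    to_region: dict[str, np.ndarray] = field(default_factory=dict)


def sliding_window_starts(n_epoch: int, n_window: int, stride: int) -> np.ndarray:
    return np.arange(0, n_epoch - n_window + 1, stride)


def so_epoch_quantifiers(
    data: np.ndarray,
    fs: float,
    trough_sample: int,
    p: int = DEFAULT_ORDER,
    freqs: np.ndarray | None = None,
    so_id: int = 0,
    method: str = "vm",
    average: str = "magnitude",
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> list[QuantifierSeries]:
    """Sliding-window quantifier series around one SO trough.

    ``data`` is the 12-channel high-passed recording (channels in the fixed
    analysis order). Extracts the 2-s epoch centred on the trough, fits one
    MVAR + GPDC per 0.5-s window with a 2-sample stride, and returns a
    QuantifierSeries per source channel (193 windows at fs=256).

    Raises ValueError when the epoch would cross a record edge; callers
    skip such events.
    """
    if freqs is None:
        freqs = default_freq_grid()
    half = int(round(EPOCH_HALF_S * fs))
    n_window = int(round(WINDOW_S * fs))
    start, stop = trough_sample - half, trough_sample + half
    if start < 0 or stop > data.shape[1]:
        raise ValueError(
            f"epoch [{start}, {stop}) crosses the record edge; event skipped"
        )
    epoch = data[:, start:stop]
    starts = sliding_window_starts(epoch.shape[1], n_window, STRIDE_SAMPLES)
    centers = (starts + n_window // 2 - half) / fs
    n_win = len(starts)
    outflow = {src: np.empty(n_win) for src in SOURCE_CHANNELS}
    to_region = {src: {r: np.empty(n_win) for r in scheme.regions}
                 for src in SOURCE_CHANNELS}
    for w, s0 in enumerate(starts):
        model = fit_mvar(epoch[:, s0 : s0 + n_window], p, method=method)
        res = gpdc(model, freqs, average=average)
        for src in SOURCE_CHANNELS:
            out, reg = quantifiers(res.pi_avg, src, scheme)
            outflow[src][w] = out
            for r, v in reg.items():
                to_region[src][r][w] = v
    return [
        QuantifierSeries(
            so_id=so_id, source=src, window_centers=centers,
            outflow=outflow[src], to_region=to_region[src],
        )
        for src in SOURCE_CHANNELS
    ]


def non_so_quantifiers(
    data: np.ndarray,
    fs: float,
    center_sample: int,
    source: str,
    p: int = DEFAULT_ORDER,
    freqs: np.ndarray | None = None,
    method: str = "vm",
    average: str = "magnitude",
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> tuple[float, dict[str, float]]:
    """Quantifiers from a single 0.5-s control window far from any SO."""
    n_window = int(round(WINDOW_S * fs))
    start = center_sample - n_window // 2
    if start < 0 or start + n_window > data.shape[1]:
        raise ValueError("non-SO window overlaps the record edge")
    model = fit_mvar(data[:, start : start + n_window], p, method=method)
    res = gpdc(model, freqs, average=average)
    return quantifiers(res.pi_avg, source, scheme)
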