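"""fNIRS signal chain: raw intensities to per-ROI haemodynamic estimates.

The chain follows the standard continuous-wave NIRS analysis path:

1. raw intensity -> optical density (OD), relative to the mean intensity;
2. motion-artifact correction by temporal derivative distribution repair
   (TDDR): robust Tukey-biweight reweighting of the OD derivative;
3. OD -> HbO/HbR concentration changes via the modified Beer-Lambert law
   (MBLL) with a partial pathlength factor PPF = DPF/PVC (default
   6/60 = 0.1);
4. a GLM per long channel and chromophore, with one regressor per
   condition (16-s boxcar convolved with the canonical double-gamma
   HRF), a discrete-cosine drift basis up to 0.01 Hz, the leading
   principal components of the short channels as superficial-signal
   nuisance regressors, and lag-1 autoregressive (Cochrane-Orcutt)
   prewhitening;
5. precision-weighted averaging of channel estimates into 12 regions of
   interest, and the HbO-HbR difference with its sign-based
   canonical / inverted / same-sign categorisation.

Short channels (< 20 mm source-detector separation) sample scalp and
skull only and are never fitted as outcome channels; long channels are
20-40 mm. No channels are excluded on quality grounds: the scalp
coupling index is reported for inspection, not used as a gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal as sps
from scipy.stats import gamma as gamma_dist

__all__ = [
    "ROIS",
    "WAVELENGTHS",
    "MontageSpec",
    "ChannelRecording",
    "PPFParams",
    "partial_pathlength_factor",
    "extinction_coefficients",
    "intensity_to_od",
    "scalp_coupling_index",
    "tddr_correct",
    "od_to_haemo",
    "canonical_hrf",
    "condition_regressor",
    "cosine_drift_basis",
    "short_channel_components",
    "build_design_matrix",
    "fit_glm_ar1",
    "aggregate_roi",
    "hbdiff",
    "FnirsPipeline",
    "process_recording",
]

#: The 12 regions of interest: bilateral inferior/middle frontal gyrus,
#: premotor and motor cortex, superior temporal gyrus, inferior parietal lobule.
ROIS: tuple[str, ...] = tuple(f"{h}{r}" for h in "LR" for r in ("IFG", "MFG", "PMC", "MC", "STG", "IPL"))

WAVELENGTHS: tuple[int, int] = (760, 850)

LN10 = float(np.log(10.0))


# --------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class MontageSpec:
    """Channel table: id, source, detector, distance, long/short flag, ROI.

    Long channels are 20-40 mm source-detector pairs and map to exactly
    one ROI; short channels (< 20 mm) sample superficial tissue.
    """

    channels: pd.DataFrame
    rois: tuple[str, ...] = ROIS

    def __post_init__(self) -> None:
        required = {"channel", "source", "detector", "distance_mm", "is_short", "roi"}
        missing = required - set(self.channels.columns)
        if missing:
            raise ValueError(f"montage table missing columns: {sorted(missing)}")
        ch = self.channels
        long_d = ch.loc[~ch["is_short"], "distance_mm"]
        if np.any((long_d <= 20) | (long_d >= 40)):
            raise ValueError("long channels must have 20 < distance < 40 mm")
        short_d = ch.loc[ch["is_short"], "distance_mm"]
        if np.any(short_d >= 20):
            raise ValueError("short channels must have distance < 20 mm")
        bad_roi = set(ch.loc[~ch["is_short"], "roi"]) - set(self.rois)
        if bad_roi:
            raise ValueError(f"long channels mapped to unknown ROIs: {sorted(bad_roi)}")

    @property
    def long_index(self) -> np.ndarray:
        return np.flatnonzero(~self.channels["is_short"].to_numpy())

    @property
    def short_index(self) -> np.ndarray:
        return np.flatnonzero(self.channels["is_short"].to_numpy())


@dataclass(frozen=True)
class ChannelRecording:
    """Two-wavelength intensity recording with events and montage.

    intensities has shape (n_channels, 2, n_times), wavelength axis in
    the order (760, 850) nm, arbitrary positive device units.
    """

    intensities: np.ndarray
    sampling_rate: float
    events: pd.DataFrame  # columns: onset, condition, duration
    montage: MontageSpec

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 3 or x.shape[1] != 2:
            raise ValueError(f"intensities must be (n_channels, 2, n_times); got {x.shape}")
        if x.shape[0] != len(self.montage.channels):
            raise ValueError("intensity channel count does not match montage")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if np.any(x <= 0):
            raise ValueError("intensities must be strictly positive")
        object.__setattr__(self, "intensities", x)

    @property
    def n_times(self) -> int:
        return self.intensities.shape[2]

    @property
    def duration(self) -> float:
        return self.n_times / self.sampling_rate


@dataclass(frozen=True)
class PPFParams:
    """Differential pathlength factor and partial volume correction.

    ppf = dpf / pvc scales the optode distance into an effective partial
    pathlength through cortex; the default 6/60 = 0.1.
    """

    dpf: float = 6.0
    pvc: float = 60.0

    @property
    def ppf(self) -> float:
        return partial_pathlength_factor(self.dpf, self.pvc)


def partial_pathlength_factor(dpf: float, pvc: float) -> float:
    """PPF = DPF / PVC; with the defaults 6 and 60 this is 0.1."""
    if pvc == 0:
        raise ValueError("partial volume correction must be non-zero")
    return dpf / pvc


def extinction_coefficients() -> pd.DataFrame:
    """Decadic molar extinction coefficients (cm^-1/M) at 760 and 850 nm.

    Loaded from the versioned table shipped with the package.
    """
    with resources.files("dyadsync.data").joinpath("extinction_coefficients.csv").open() as fh:
        return pd.read_csv(fh, comment="#").set_index("wavelength_nm")


# --------------------------------------------------------------------------
# preprocessing


def intensity_to_od(intensities: np.ndarray, baseline: np.ndarray | None = None) -> np.ndarray:
    """OD(t) = -ln(I(t) / I0) with I0 the per-channel mean intensity.

    ``baseline`` overrides the default whole-recording mean (same shape
    as the intensity array minus the time axis).
    """
    x = np.asarray(intensities, dtype=float)
    if np.any(x <= 0):
        bad = np.unique(np.argwhere(x <= 0)[:, 0])
        raise ValueError(f"non-positive intensity in channel(s) {bad.tolist()}")
    i0 = x.mean(axis=-1, keepdims=True) if baseline is None else np.asarray(baseline, float)[..., None]
    return -np.log(x / i0)


def scalp_coupling_index(rec: ChannelRecording, band: tuple[float, float] = (0.7, 1.5)) -> np.ndarray:
    """Per-channel correlation of the two wavelengths in the cardiac band.

    A channel with good scalp contact shows the same cardiac pulsation at
    both wavelengths, giving values near 1.
    """
    if rec.duration < 30.0:
        raise ValueError("recording must be at least 30 s for the scalp coupling index")
    nyq = rec.sampling_rate / 2.0
    lo, hi = band
    hi = min(hi, 0.95 * nyq)
    if lo >= hi:
        raise ValueError("cardiac band collapsed; sampling rate too low")
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    od = intensity_to_od(rec.intensities)
    filtered = sps.sosfiltfilt(sos, od, axis=-1)
    a, b = filtered[:, 0, :], filtered[:, 1, :]
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=-1) * (b**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        sci = np.where(denom > 0, (a * b).sum(axis=-1) / denom, 0.0)
    return sci


def _tddr_one(x: np.ndarray, sampling_rate: float, tune: float = 4.685, max_iter: int = 50, tol: float = 1e-6) -> np.ndarray:
    mean = x.mean()
    x = x - mean
    fc = 0.5 * 2.0 / sampling_rate
    if fc < 1.0:
        b, a = sps.butter(3, fc)
        low = sps.filtfilt(b, a, x, padlen=0)
    else:
        low = x.copy()
    high = x - low
    deriv = np.diff(low)
    w = np.ones_like(deriv)
    for _ in range(max_iter):
        w_prev = w
        mu = float(np.sum(w * deriv) / np.sum(w))
        dev = np.abs(deriv - mu)
        sigma = 1.4826 * float(np.median(dev))
        if sigma == 0.0:
            w = np.ones_like(deriv)
            break
        r = dev / (sigma * tune)
        w = ((1.0 - r**2) * (r < 1.0)) ** 2
        if np.max(np.abs(w - w_prev)) < tol:
            break
    corrected_deriv = w * (deriv - mu)
    low_corrected = np.concatenate([[0.0], np.cumsum(corrected_deriv)])
    low_corrected -= low_corrected.mean()
    return low_corrected + high + mean


def tddr_correct(od: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Temporal derivative distribution repair, applied per channel.

    The signal is split at 0.5 Hz; the low-frequency part's temporal
    derivative is robust-reweighted (iterated Tukey biweight, tuning
    constant 4.685 x a MAD-based robust SD, iterated to weight
    convergence), re-integrated and recombined with the high-frequency
    residual. Spike and baseline-shift artifacts are suppressed while
    slow haemodynamics pass through nearly unchanged.
    """
    x = np.asarray(od, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("OD input to TDDR must be finite")
    flat = x.reshape(-1, x.shape[-1])
    out = np.empty_like(flat)
    for i, row in enumerate(flat):
        out[i] = _tddr_one(row, sampling_rate)
    return out.reshape(x.shape)


def od_to_haemo(od: np.ndarray, distance_mm, ppf: PPFParams | float = PPFParams()) -> np.ndarray:
    """Invert the MBLL: OD at (760, 850) nm -> (HbO, HbR) concentration change.

    ``od`` has shape (..., 2, n_times) with the wavelength axis second to
    last; the result has the same shape with (HbO, HbR) in its place,
    in mol/L. The OD input is natural-log optical density (as returned
    by :func:`intensity_to_od`), so the decadic extinction coefficients
    are scaled by ln(10) before solving the per-timepoint 2x2 system

        OD_lambda = ln(10) * eps_lambda,X * C_X * d * ppf.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim < 2 or od.shape[-2] != 2:
        raise ValueError("od must have a wavelength axis of size 2 (760, 850 nm)")
    ppf_val = ppf.ppf if isinstance(ppf, PPFParams) else float(ppf)
    eps = extinction_coefficients()
    e = np.array(
        [
            [eps.loc[WAVELENGTHS[0], "hbo"], eps.loc[WAVELENGTHS[0], "hbr"]],
            [eps.loc[WAVELENGTHS[1], "hbo"], eps.loc[WAVELENGTHS[1], "hbr"]],
        ]
    )
    if abs(np.linalg.det(e)) < 1e-12:
        raise ValueError("extinction coefficient matrix is singular")
    d_cm = np.asarray(distance_mm, dtype=float) / 10.0
    inv = np.linalg.inv(e) / LN10
    scale = 1.0 / (d_cm * ppf_val)
    haemo = np.einsum("ij,...jt->...it", inv, od)
    return haemo * np.reshape(scale, scale.shape + (1, 1)) if np.ndim(scale) else haemo * scale


def forward_mbll(hbo: np.ndarray, hbr: np.ndarray, distance_mm: float, ppf: PPFParams | float = PPFParams()) -> np.ndarray:
    """Forward MBLL: concentration changes -> decadic OD at (760, 850) nm.

    Exact inverse of :func:`od_to_haemo` up to the ln(10) convention:
    this returns base-10 OD suitable for I = I0 * 10**(-OD), which after
    -ln(I/I0) conversion reproduces the haemo input through od_to_haemo.
    """
    ppf_val = ppf.ppf if isinstance(ppf, PPFParams) else float(ppf)
    eps = extinction_coefficients()
    d_cm = float(distance_mm) / 10.0
    c = np.stack([hbo, hbr])
    e = np.array(
        [
            [eps.loc[WAVELENGTHS[0], "hbo"], eps.loc[WAVELENGTHS[0], "hbr"]],
            [eps.loc[WAVELENGTHS[1], "hbo"], eps.loc[WAVELENGTHS[1], "hbr"]],
        ]
    )
    return (e @ c) * d_cm * ppf_val


# --------------------------------------------------------------------------
# GLM


def canonical_hrf(t: np.ndarray, peak_delay: float = 6.0, undershoot_delay: float = 16.0, ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response function.

    Gamma densities with shape = delay (scale 1 s): a peak at ~6 s minus
    a 1/6-scaled undershoot peaking at ~16 s.
    """
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, a=peak_delay) - ratio * gamma_dist.pdf(t, a=undershoot_delay)
    return h


def condition_regressor(
    onsets: np.ndarray,
    n_times: int,
    sampling_rate: float,
    duration_s: float = 16.0,
    oversample: int = 10,
) -> np.ndarray:
    """Unit-peak regressor: 16-s boxcars at the onsets convolved with the HRF.

    Built on an oversampled grid then resampled to the recording grid;
    scaled so an isolated event peaks at 1, making GLM betas directly
    interpretable as response amplitudes.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    if onsets.size == 0:
        raise ValueError("no events for condition regressor")
    fine_rate = sampling_rate * oversample
    n_fine = n_times * oversample
    hrf_t = np.arange(0.0, 33.0, 1.0 / fine_rate)
    kernel = canonical_hrf(hrf_t)
    box_len = max(1, int(round(duration_s * fine_rate)))
    event_response = np.convolve(np.ones(box_len), kernel) / fine_rate
    peak = np.max(np.abs(event_response))
    stick = np.zeros(n_fine)
    for onset in onsets:
        idx = int(round(onset * fine_rate))
        if 0 <= idx < n_fine:
            stick[idx] += 1.0
    fine = np.convolve(stick, event_response)[:n_fine] / peak
    return fine[::oversample][:n_times]


def cosine_drift_basis(n_times: int, sampling_rate: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """Discrete-cosine drift regressors with frequencies up to ``cutoff_hz``.

    DCT-II basis; component k has frequency k / (2 T). Columns are
    mutually orthogonal. Shape (n_times, n_components); may be empty for
    short recordings.
    """
    t_total = n_times / sampling_rate
    k_max = int(np.floor(2.0 * t_total * cutoff_hz))
    i = np.arange(n_times)
    cols = [np.cos(np.pi * k * (2 * i + 1) / (2 * n_times)) for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n_times, 0))


def short_channel_components(short_haemo: np.ndarray, variance: float = 0.95, n_components: int | None = None) -> np.ndarray:
    """Leading principal components of the short-channel signals.

    ``short_haemo`` is (n_signals, n_times): typically HbO and HbR of
    every short channel stacked. Components are retained up to the
    requested cumulative variance fraction (default 95%) unless an
    explicit count is given. Returns (n_times, n_components).
    """
    x = np.asarray(short_haemo, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    if var.sum() == 0:
        return np.empty((x.shape[1], 0))
    if n_components is None:
        cum = np.cumsum(var) / var.sum()
        n_components = int(np.searchsorted(cum, variance) + 1)
    n_components = min(n_components, len(s))
    return vt[:n_components].T


def build_design_matrix(
    events: pd.DataFrame,
    n_times: int,
    sampling_rate: float,
    duration_s: float = 16.0,
    drift_highpass_hz: float = 0.01,
    short_channel_signals: np.ndarray | None = None,
    short_pc_variance: float = 0.95,
    short_pc_count: int | None = None,
) -> pd.DataFrame:
    """Assemble the GLM design matrix.

    Columns: one unit-peak HRF regressor per condition, a cosine drift
    basis up to ``drift_highpass_hz``, short-channel principal
    components (if provided), and a constant.
    """
    if len(events) == 0:
        raise ValueError("events table is empty")
    cols: dict[str, np.ndarray] = {}
    for cond, sub in events.groupby("condition", sort=True):
        onsets = sub["onset"].to_numpy(dtype=float)
        if len(np.unique(np.round(onsets * sampling_rate))) < len(onsets):
            import warnings

            warnings.warn(f"overlapping identical events in condition {cond!r}", stacklevel=2)
        cols[f"cond_{cond}"] = condition_regressor(onsets, n_times, sampling_rate, duration_s)
    drift = cosine_drift_basis(n_times, sampling_rate, drift_highpass_hz)
    for k in range(drift.shape[1]):
        cols[f"drift_{k + 1}"] = drift[:, k]
    if short_channel_signals is not None and short_channel_signals.size:
        pcs = short_channel_components(short_channel_signals, short_pc_variance, short_pc_count)
        for k in range(pcs.shape[1]):
            cols[f"short_pc_{k + 1}"] = pcs[:, k]
    cols["constant"] = np.ones(n_times)
    return pd.DataFrame(cols)


def fit_glm_ar1(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    """GLM with lag-1 autoregressive prewhitening (Cochrane-Orcutt).

    OLS residuals give the AR(1) coefficient rho; y and X are then
    transformed (x_t - rho x_{t-1}, first observation dropped) and
    refitted, and standard errors are taken from the prewhitened fit.
    Returns a table (regressor, beta, se, rho).
    """
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: y has {y.shape[0]}, X has {Xv.shape[0]} rows")
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient")
    ols = sm.OLS(y, Xv).fit()
    resid = ols.resid
    denom = float(resid[:-1] @ resid[:-1])
    # an essentially perfect fit leaves only float round-off in the
    # residuals; treat that as white noise rather than estimating rho from it
    negligible = denom <= 1e-12 * max(float(y @ y), 1e-300)
    rho = float(resid[1:] @ resid[:-1] / denom) if denom > 0 and not negligible else 0.0
    if abs(rho) >= 1.0:
        raise ValueError(f"estimated AR(1) coefficient {rho:.3f} outside (-1, 1)")
    yw = y[1:] - rho * y[:-1]
    Xw = Xv[1:] - rho * Xv[:-1]
    fit = sm.OLS(yw, Xw).fit()
    return pd.DataFrame(
        {
            "regressor": list(X.columns),
            "beta": fit.params,
            "se": fit.bse,
            "rho": rho,
        }
    )


def aggregate_roi(estimates: pd.DataFrame, weighting: str = "inverse_variance") -> pd.DataFrame:
    """Precision-weighted average of channel betas within each ROI.

    ``estimates`` needs columns (roi, beta, se) plus any grouping columns
    already subset. Default weights are 1/SE^2 (inverse variance), with
    SE_roi = sqrt(1 / sum w); ``weighting="inverse_se"`` uses 1/SE.
    """
    if weighting not in ("inverse_variance", "inverse_se"):
        raise ValueError(f"unknown weighting {weighting!r}")
    rows = []
    for roi, sub in estimates.groupby("roi", sort=True):
        if len(sub) == 0:
            raise ValueError(f"ROI {roi} has no channel estimates")
        se = sub["se"].to_numpy(dtype=float)
        beta = sub["beta"].to_numpy(dtype=float)
        w = 1.0 / se**2 if weighting == "inverse_variance" else 1.0 / se
        beta_roi = float((w * beta).sum() / w.sum())
        se_roi = float(np.sqrt(1.0 / w.sum())) if weighting == "inverse_variance" else float(
            np.sqrt((w**2 * se**2).sum() / w.sum() ** 2)
        )
        rows.append({"roi": roi, "beta": beta_roi, "se": se_roi, "n_channels": len(sub)})
    return pd.DataFrame(rows)


def hbdiff(hbo_beta: float, hbr_beta: float) -> tuple[float, str]:
    """HbO - HbR difference and its sign category.

    canonical: HbO > 0 and HbR < 0 (usual functional response);
    inverted: HbO < 0 and HbR > 0 (negative-BOLD-like);
    same_sign: both positive or both negative, which may reflect blood
    pressure or extracerebral changes rather than cortical activation.
    """
    if not (np.isfinite(hbo_beta) and np.isfinite(hbr_beta)):
        raise ValueError("hbdiff requires finite inputs")
    diff = hbo_beta - hbr_beta
    if hbo_beta > 0 and hbr_beta < 0:
        cat = "canonical"
    elif hbo_beta < 0 and hbr_beta > 0:
        cat = "inverted"
    else:
        cat = "same_sign"
    return float(diff), cat


# --------------------------------------------------------------------------
# pipeline


@dataclass
class FnirsPipeline:
    """Configured end-to-end chain from a ChannelRecording to ROI estimates.

    Parameters mirror the processing stages; ``apply_tddr=False`` skips
    motion correction (useful on noise-free simulations),
    ``use_short_channels=False`` disables the superficial-signal
    regressors.
    """

    ppf: PPFParams = field(default_factory=PPFParams)
    duration_s: float = 16.0
    drift_highpass_hz: float = 0.01
    short_pc_variance: float = 0.95
    short_pc_count: int | None = None
    use_short_channels: bool = True
    apply_tddr: bool = True
    weighting: str = "inverse_variance"

    def channel_estimates(self, rec: ChannelRecording) -> pd.DataFrame:
        """Per long-channel, per-condition HbO/HbR betas with SEs."""
        montage = rec.montage
        od = intensity_to_od(rec.intensities)
        if self.apply_tddr:
            od = tddr_correct(od, rec.sampling_rate)
        distances = montage.channels["distance_mm"].to_numpy(dtype=float)
        haemo = np.empty_like(od)  # (n_channels, 2=(HbO,HbR), n_times)
        for i in range(od.shape[0]):
            haemo[i] = od_to_haemo(od[i], distances[i], self.ppf)

        short_signals = None
        if self.use_short_channels and len(montage.short_index):
            sh = haemo[montage.short_index]
            short_signals = sh.reshape(-1, sh.shape[-1])
        X = build_design_matrix(
            rec.events,
            rec.n_times,
            rec.sampling_rate,
            duration_s=self.duration_s,
            drift_highpass_hz=self.drift_highpass_hz,
            short_channel_signals=short_signals,
            short_pc_variance=self.short_pc_variance,
            short_pc_count=self.short_pc_count,
        )
        cond_cols = [c for c in X.columns if c.startswith("cond_")]
        rows = []
        for ci in montage.long_index:
            info = montage.channels.iloc[ci]
            for chrom_idx, chrom in enumerate(("hbo", "hbr")):
                fit = fit_glm_ar1(haemo[ci, chrom_idx], X).set_index("regressor")
                for col in cond_cols:
                    rows.append(
                        {
                            "channel": info["channel"],
                            "roi": info["roi"],
                            "condition": col.removeprefix("cond_"),
                            "chromophore": chrom,
                            "beta": fit.loc[col, "beta"],
                            "se": fit.loc[col, "se"],
                        }
                    )
        return pd.DataFrame(rows)

    def roi_estimates(self, rec: ChannelRecording) -> pd.DataFrame:
        """ROI x condition HbO/HbR betas, HbO-HbR difference and category."""
        per_channel = self.channel_estimates(rec)
        rows = []
        for (cond, chrom), sub in per_channel.groupby(["condition", "chromophore"], sort=True):
            agg = aggregate_roi(sub, weighting=self.weighting)
            agg["condition"] = cond
            agg["chromophore"] = chrom
            rows.append(agg)
        wide = (
            pd.concat(rows)
            .pivot(index=["roi", "condition"], columns="chromophore", values=["beta", "se"])
        )
        out = []
        for (roi, cond), r in wide.iterrows():
            diff, cat = hbdiff(r[("beta", "hbo")], r[("beta", "hbr")])
            out.append(
                {
                    "roi": roi,
                    "condition": cond,
                    "hbo_beta": r[("beta", "hbo")],
                    "hbo_se": r[("se", "hbo")],
                    "hbr_beta": r[("beta", "hbr")],
                    "hbr_se": r[("se", "hbr")],
                    "hbdiff": diff,
                    "category": cat,
                }
            )
        return pd.DataFrame(out)


def process_recording(rec: ChannelRecording, **kwargs) -> pd.DataFrame:
    """Run the full chain with keyword-configured :class:`FnirsPipeline`."""
    return FnirsPipeline(**kwargs).roi_estimates(rec)


# --------------------------------------------------------------------------
# recording I/O (synthetic recording directory format)


def save_recording(rec: ChannelRecording, outdir: str | Path) -> None:
    """Write a recording as channels.csv + per-wavelength intensity CSVs +
    events.csv + meta.json."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec.montage.channels.to_csv(outdir / "channels.csv", index=False)
    for wi, wl in enumerate(WAVELENGTHS):
        pd.DataFrame(rec.intensities[:, wi, :]).to_csv(outdir / f"intensities_{wl}.csv", index=False, header=False)
    rec.events.to_csv(outdir / "events.csv", index=False)
    (outdir / "meta.json").write_text(json.dumps({"sampling_rate": rec.sampling_rate, "wavelengths": WAVELENGTHS}))


def load_recording(indir: str | Path) -> ChannelRecording:
    import json

    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    channels = pd.read_csv(indir / "channels.csv")
    events = pd.read_csv(indir / "events.csv")
    mats = [pd.read_csv(indir / f"intensities_{wl}.csv", header=None).to_numpy() for wl in WAVELENGTHS]
    intensities = np.stack(mats, axis=1)
    return ChannelRecording(
        intensities=intensities,
        sampling_rate=float(meta["sampling_rate"]),
        events=events,
        montage=MontageSpec(channels=channels),
    )
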