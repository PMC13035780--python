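"""Synthetic resting-state EEG cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
groups (experimental / control) x two sessions (T0 baseline, T1 after
treatment), n = 40 per group, six 10-20 electrodes at 1 kHz, 20 s of
analyzable signal per session.

Single-channel model
--------------------
A signal with target band fractions ``f = (f_delta, f_theta, f_alpha,
f_beta)`` (summing to 1) is built as

    x(t) = sum_b sqrt(f_b) * [ sqrt(c) * z_b(t) + sqrt(1 - c) * s_b(t) ]

where ``z_b`` is unit-variance Gaussian noise spread over band ``b``
(FFT-domain masking shaped by a continuous spectral envelope) and ``s_b``
is a unit-variance sinusoid inside the band (seeded random phase;
channel-specific frequency offset, see :func:`synth_signal`); ``c`` is
the *complexity level* in [0, 1]: ``c = 1`` gives fully spread within-
band noise, ``c = 0`` four deterministic oscillations.  Because the
oscillation sits inside its own band, the band fractions are preserved
at every complexity level while Lempel-Ziv complexity and approximate
entropy increase monotonically with ``c``.

Cohort model
------------
Per-subject band fractions are Dirichlet perturbations of the group-level
targets (concentration 80 gives between-subject SDs of roughly 3.5-5.5
percentage points, matching the reported group SDs).  The infarcted
hemisphere's electrodes (odd labels if the infarct is left-sided) use the
"affected" targets; the other three use "healthy" targets.  Baseline
NIHSS is a rounded group-specific normal clipped to the 5-20 inclusion
window; the T1 score derives from a linear-Gaussian link between the
improvement (dNIHSS = NIHSS_T0 - NIHSS_T1) and the subject's drawn
affected-hemisphere alpha/beta ratio at T1, tuned so the realized
correlation hits a target Pearson r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numpy.random import SeedSequence, default_rng

from .errors import ValidationError
from .io import (
    EEGRecording,
    REQUIRED_CHANNELS,
    SubjectRecord,
    write_cohort_csv,
    write_edf,
)

# ---------------------------------------------------------------------------
# Canonical bands
# ---------------------------------------------------------------------------

BAND_NAMES = ("delta", "theta", "alpha", "beta")

#: Canonical EEG band edges in Hz, half-open [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Base frequency of the deterministic oscillation of each band.  Integer
#: frequencies sit on the 1-Hz Welch grid, well inside their band, so the
#: oscillation does not leak across band edges under the default analysis.
BAND_OSC_FREQS = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 21.0}


def _spectral_envelope(fracs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous piecewise-linear power density realizing the targets.

    Real EEG spectra are continuous across band edges; a blockwise-flat
    density would put a discontinuity exactly where the Welch estimator's
    spectral kernel straddles a boundary (biasing the recovered fractions),
    and would pile delta power onto the 1 Hz edge where the band-pass
    filter's skirt erodes it.  Each band therefore gets a "tent" profile:
    the density at a shared edge is the smaller of the two neighbouring
    flat densities (continuity with a shallow junction), the density at
    the outer edges (1 and 30 Hz) is a fraction of the band's flat
    density, and a mid-band node takes up the remaining mass so that the
    trapezoid integral over each band equals its target fraction exactly.

    Returns ``(node_freqs, node_densities)`` for ``np.interp``.
    """
    edges = np.array([1.0, 4.0, 8.0, 13.0, 30.0])
    widths = np.diff(edges)  # (3, 4, 5, 17)
    flat = fracs / widths
    e = np.empty(5)
    e[0] = 0.2 * flat[0]
    e[1:4] = np.minimum(flat[:-1], flat[1:])
    e[4] = 0.5 * flat[3]
    mids = (edges[:-1] + edges[1:]) / 2
    # tent integral: (w/4) * (e_lo + 2 m + e_hi) = f  =>  solve for m
    m = np.clip((4 * fracs / widths - e[:-1] - e[1:]) / 2, 0.0, None)
    node_f = np.empty(9)
    node_f[0::2] = edges
    node_f[1::2] = mids
    node_d = np.empty(9)
    node_d[0::2] = e
    node_d[1::2] = m
    return node_f, node_d


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if self.name not in BANDS:
            raise ValidationError(f"unknown band {self.name!r}")
        lo, hi = BANDS[self.name]
        if (self.lo, self.hi) != (lo, hi):
            raise ValidationError(
                f"band {self.name} is fixed at [{lo}, {hi}) Hz"
            )


def band_specs() -> tuple[BandSpec, ...]:
    return tuple(BandSpec(n, *BANDS[n]) for n in BAND_NAMES)


# ---------------------------------------------------------------------------
# Calibration defaults (group-level targets)
# ---------------------------------------------------------------------------

def _norm(v) -> tuple[float, ...]:
    v = np.asarray(v, dtype=float)
    return tuple(v / v.sum())

# Group-mean relative band powers (percent, affected hemisphere) reported
# for this cohort; rows renormalized to sum exactly to 1.
EXPERIMENTAL_T0_BANDS = _norm((46.3, 25.1, 18.2, 11.3))
EXPERIMENTAL_T1_BANDS = _norm((36.3, 21.8, 24.5, 18.6))
CONTROL_T0_BANDS = _norm((42.8, 23.7, 17.9, 11.6))

# The control group showed no significant band changes over treatment, only
# a slight non-significant theta decrease; its T1 target is therefore the T0
# profile with 0.5 points moved out of theta (spread over the other bands).
def _slight_theta_decrease(fracs, amount=0.005):
    f = np.asarray(fracs, dtype=float).copy()
    f[1] -= amount
    others = [0, 2, 3]
    f[others] += amount * f[others] / f[others].sum()
    return tuple(f / f.sum())

CONTROL_T1_BANDS = _slight_theta_decrease(CONTROL_T0_BANDS)

# No healthy-hemisphere group values are reported (only that nothing changed
# there); healthy-hemisphere targets are set to the control-group baseline
# profile for every group and session.  This is an assumption.
HEALTHY_BANDS = CONTROL_T0_BANDS

DEFAULT_BAND_FRACTIONS: dict[tuple[str, str, str], tuple[float, ...]] = {}
for _g, _s, _t in (
    ("experimental", "T0", EXPERIMENTAL_T0_BANDS),
    ("experimental", "T1", EXPERIMENTAL_T1_BANDS),
    ("control", "T0", CONTROL_T0_BANDS),
    ("control", "T1", CONTROL_T1_BANDS),
):
    DEFAULT_BAND_FRACTIONS[(_g, _s, "affected")] = _t
    DEFAULT_BAND_FRACTIONS[(_g, _s, "healthy")] = HEALTHY_BANDS

# Complexity levels per (group, session).  Together with the nonlinear
# analysis rates (see qeeg.nonlinear) these are calibrated once so that
# the pipeline's normalized LZC / ApEn group means sit in the reported
# ranges (LZC ~0.41 -> 0.57, ApEn ~0.79 -> 0.97 in the experimental group,
# flat in the control group); see docs/methods.md for the calibration and
# its limits — the T0->T1 complexity increase is carried mostly by the
# spectral shift and is somewhat smaller than reported.
DEFAULT_COMPLEXITY: dict[tuple[str, str], float] = {
    ("experimental", "T0"): 0.20,
    ("experimental", "T1"): 0.90,
    ("control", "T0"): 0.20,
    ("control", "T1"): 0.20,
}


@dataclass
class NIHSSModel:
    """Linear-Gaussian link dNIHSS = intercept + slope * feature + noise.

    By default the intercept/slope/noise are derived per group from the
    target group mean and SD of dNIHSS and the target Pearson correlation
    with the designated feature (the realized affected-hemisphere
    alpha/beta ratio at T1): the systematic SD is ``target_corr * delta_sd``
    and the noise SD is ``delta_sd * sqrt(1 - target_corr**2)``.  Explicit
    ``intercept``/``slope``/``noise_sd`` override the derivation.  Integer
    rounding and the nihss_t1 >= 0 clip slightly attenuate the realized
    correlation.
    """

    feature: str = "alpha_beta_ratio"
    target_corr: float = 0.632
    delta_mean: Mapping[str, float] = field(
        default_factory=lambda: {"experimental": 7.2, "control": 4.5})
    delta_sd: Mapping[str, float] = field(
        default_factory=lambda: {"experimental": 2.1, "control": 1.8})
    # baseline NIHSS: rounded normal clipped to the 5-20 inclusion window
    t0_mean: Mapping[str, float] = field(
        default_factory=lambda: {"experimental": 13.0, "control": 12.5})
    t0_sd: Mapping[str, float] = field(
        default_factory=lambda: {"experimental": 3.2, "control": 2.5})
    intercept: float | None = None
    slope: float | None = None
    noise_sd: float | None = None

    def __post_init__(self):
        if not -1.0 < self.target_corr < 1.0:
            raise ValidationError("target_corr must be in (-1, 1)")


@dataclass
class CohortSpec:
    """Everything needed to synthesize a reproducible two-group cohort."""

    n_per_group: int = 40
    seed: int = 0
    fs: float = 1000.0
    # The study protocol records minutes of resting EEG and *selects* five
    # clean 4-s segments; 28 s gives the selector two spare windows.
    duration_s: float = 28.0
    band_fractions: Mapping[tuple[str, str, str], Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_FRACTIONS))
    complexity_level: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLEXITY))
    complexity_jitter_sd: float = 0.04
    # 80 gives between-subject band-fraction SDs of ~3.5-5.5 percentage
    # points, matching the reported group SDs (roughly 3-8 points).
    dirichlet_concentration: float = 80.0
    # 20 uV RMS resting EEG: a clean signal then sits comfortably below the
    # 200 uV peak-to-peak artifact threshold, so epoch rejection acts on
    # injected artifacts rather than on ordinary slow-wave excursions
    # (which would bias the delta fraction of the retained epochs).
    signal_rms_uv: float = 20.0
    nihss_model: NIHSSModel = field(default_factory=NIHSSModel)
    artifact_rate: float = 0.0  # expected amplitude artifacts per recording
    artifact_amp_uv: float = 500.0
    # Pre-adjust band weights for the analysis chain's estimator bias (see
    # compensated_band_weights).  Disable for null simulations where any
    # common bias cancels between the groups and speed matters.
    compensate: bool = True

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        for key, fr in self.band_fractions.items():
            fr = np.asarray(fr, dtype=float)
            if fr.shape != (4,) or np.any(fr < 0):
                raise ValidationError(
                    f"band_fractions[{key}] must be 4 nonnegative values")
            if abs(fr.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"band_fractions[{key}] sums to {fr.sum():.12f}, not 1")
        for key, c in self.complexity_level.items():
            if not 0.0 <= c <= 1.0:
                raise ValidationError(
                    f"complexity_level[{key}]={c} outside [0, 1]")
        if self.dirichlet_concentration <= 0:
            raise ValidationError("dirichlet_concentration must be > 0")


# ---------------------------------------------------------------------------
# Expected-value compensation of the analysis chain
# ---------------------------------------------------------------------------

_MODEL_DF = 0.05  # fine frequency grid step for the expectation model, Hz


@lru_cache(maxsize=8)
def _analysis_response(fs: float, window_length_s: float, filtered: bool):
    """Spectral response of the default analysis chain.

    Returns ``(bins, grid, resp, filt_grid, kernel_interp)`` where ``resp``
    maps a true power density sampled on ``grid`` to the *expected* Welch
    PSD at the integer-Hz ``bins`` (Hann window of ``window_length_s``),
    ``filt_grid`` is the power response of the zero-phase 1-45 Hz
    Butterworth band-pass on ``grid``, and ``kernel_interp(f)`` evaluates
    the window's normalized power kernel at offset ``f``.
    """
    from scipy.signal import butter, get_window, sosfreqz

    grid = np.arange(0.0, 35.0 + _MODEL_DF / 2, _MODEL_DF)
    nper = int(round(window_length_s * fs))
    pad = int(round(fs / _MODEL_DF))
    w = get_window("hann", nper)
    W = np.abs(np.fft.rfft(w, n=pad)) ** 2
    kfreq = np.arange(W.size) * _MODEL_DF
    norm = (2.0 * W[1:].sum() + W[0]) * _MODEL_DF  # symmetric kernel integral
    keep = kfreq <= 8.0  # mainlobe + first sidelobes; beyond is < -40 dB
    k_off, k_val = kfreq[keep], W[keep] / norm

    def kernel(offsets):
        return np.interp(np.abs(offsets), k_off, k_val, right=0.0)

    bins = np.arange(0.0, 36.0)
    resp = kernel(bins[:, None] - grid[None, :]) * _MODEL_DF
    if filtered:
        sos = butter(4, [1.0, 45.0], btype="bandpass", fs=fs, output="sos")
        _, h = sosfreqz(sos, worN=grid, fs=fs)
        filt = np.abs(h) ** 4  # forward-backward filtering: |H|^2 on PSD
    else:
        filt = np.ones_like(grid)
    return bins, grid, resp, filt, kernel


def expected_measured_fractions(weights, complexity_level: float,
                                fs: float = 1000.0,
                                window_length_s: float = 1.0,
                                filtered: bool = True,
                                osc_offset_hz: float = 0.0) -> np.ndarray:
    """Expected pipeline-measured band fractions for given band weights.

    Convolves the generator's true spectral density (tent envelope plus
    oscillation lines) with the Welch window's power kernel and the
    band-pass power response, then applies the coverage-weighted band
    integration — i.e. the expectation of what
    :func:`qeeg.spectral.band_rpsd` reports.
    """
    from .spectral import band_rpsd

    weights = np.asarray(weights, dtype=float)
    bins, grid, resp, filt, kernel = _analysis_response(
        float(fs), float(window_length_s), bool(filtered))
    env_f, env_d = _spectral_envelope(weights)
    dens = np.interp(grid, env_f, env_d, left=0.0, right=0.0)
    dens[(grid < 1.0) | (grid >= 30.0)] = 0.0
    psd = resp @ (complexity_level * dens * filt)
    if complexity_level < 1.0:
        for name, w_b in zip(BAND_NAMES, weights):
            if w_b == 0.0:
                continue
            f0 = BAND_OSC_FREQS[name] + osc_offset_hz
            t_filt = float(np.interp(f0, grid, filt))
            psd += ((1.0 - complexity_level) * w_b * t_filt
                    * kernel(bins - f0))
    rpsd, _ = band_rpsd(bins, psd)
    return np.array([rpsd[b] for b in BAND_NAMES])


def compensated_band_weights(band_fractions, complexity_level: float,
                             fs: float = 1000.0,
                             window_length_s: float = 1.0,
                             filtered: bool = True,
                             osc_offset_hz: float = 0.0,
                             n_iter: int = 4) -> np.ndarray:
    """Band weights whose *expected measured* fractions equal the targets.

    Fixed-point iteration on the expectation model above; the returned
    weights differ from the targets by at most a few percentage points
    (they absorb the spectral-kernel and filter-skirt biases of the
    default analysis chain).
    """
    target = np.asarray(band_fractions, dtype=float)
    g = target.copy()
    for _ in range(n_iter):
        m = expected_measured_fractions(g, complexity_level, fs,
                                        window_length_s, filtered,
                                        osc_offset_hz)
        g = g * np.where(m > 1e-12, target / np.maximum(m, 1e-12), 1.0)
        s = g.sum()
        if s > 0:
            g = g / s
    return g


# ---------------------------------------------------------------------------
# Single-channel synthesis
# ---------------------------------------------------------------------------

def synth_signal(band_fractions, complexity_level: float, duration_s: float,
                 fs: float, seed=None, compensate: bool = True,
                 osc_offset_hz: float = 0.0) -> np.ndarray:
    """One channel of unit-variance synthetic EEG (see module docstring).

    Parameters
    ----------
    band_fractions : 4 floats summing to 1
        Target relative power in delta/theta/alpha/beta.
    complexity_level : float in [0, 1]
        Mixing weight of spread band noise vs the deterministic per-band
        oscillations (sinusoids with seeded random phase).
    seed : int, SeedSequence or Generator, optional
    compensate : bool
        When True (default) the band weights are pre-adjusted with
        :func:`compensated_band_weights` so that the *measured* rPSD under
        the default analysis chain (1-45 Hz zero-phase band-pass, 1-s Hann
        Welch windows) is unbiased for the targets — the reported group
        values this generator emulates are themselves Welch-measured
        quantities.  With ``compensate=False`` the realized band variances
        equal the targets exactly instead (Parseval sense).
    osc_offset_hz : float
        Added to every band's oscillation frequency.  The cohort generator
        gives each channel of a recording a distinct offset so the
        oscillations are orthogonal across channels over the recording and
        average referencing mixes their power deterministically (identical
        tones would be common mode and cancel).

    Returns
    -------
    ndarray, shape (round(duration_s * fs),)
        Unit-variance signal whose expected rPSD in band ``b`` is
        ``band_fractions[b]``.
    """
    fracs = np.asarray(band_fractions, dtype=float)
    if fracs.shape != (4,) or np.any(fracs < 0):
        raise ValidationError("band_fractions must be 4 nonnegative values")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"band_fractions sum to {fracs.sum():.12f}, expected 1")
    if not 0.0 <= complexity_level <= 1.0:
        raise ValidationError("complexity_level must lie in [0, 1]")
    if duration_s < 4.0:
        raise ValidationError("duration_s must be >= 4 (one epoch)")
    if fs < 60.0:
        raise ValidationError("fs must be >= 60 Hz (Nyquist above 30 Hz)")

    rng = seed if isinstance(seed, np.random.Generator) else default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    if compensate:
        fracs = compensated_band_weights(
            fracs, complexity_level, fs, osc_offset_hz=osc_offset_hz)
    env_f, env_d = _spectral_envelope(fracs)

    # Noise part, built directly in the frequency domain: complex Gaussian
    # coefficients on the in-band bins, amplitude-shaped by the continuous
    # envelope, each band normalized by Parseval so its realized variance
    # is exactly complexity_level * f_b.
    spec = np.zeros(freqs.size, dtype=complex)
    t = np.arange(n) / fs
    x_osc = np.zeros(n)
    for name, f_b in zip(BAND_NAMES, fracs):
        lo, hi = BANDS[name]
        mask = (freqs >= lo) & (freqs < hi)
        nb = int(mask.sum())
        if f_b == 0.0 or nb == 0:
            continue
        coef = (rng.standard_normal(nb) + 1j * rng.standard_normal(nb))
        coef *= np.sqrt(np.interp(freqs[mask], env_f, env_d))
        # realized time-domain variance of irfft(spec): 2*sum|c|^2 / n^2
        power = 2.0 * np.sum(np.abs(coef) ** 2) / n ** 2
        if power > 0:
            coef *= np.sqrt(complexity_level * f_b / power)
        spec[mask] = coef
        if complexity_level < 1.0:
            f0 = BAND_OSC_FREQS[name] + osc_offset_hz
            s = np.sin(2.0 * np.pi * f0 * t + rng.uniform(0.0, 2.0 * np.pi))
            sd = s.std()
            if sd > 0:
                x_osc += np.sqrt((1.0 - complexity_level) * f_b) * (s / sd)
    x = np.fft.irfft(spec, n) + x_osc
    sd = x.std()
    return x / sd if sd > 0 else x


def _inject_artifacts(data: np.ndarray, rate: float, amp: float, fs: float,
                      rng: np.random.Generator) -> None:
    """Add brief high-amplitude spikes in-place (epoch-rejection fodder)."""
    n_ch, n = data.shape
    n_art = rng.poisson(rate)
    width = max(int(0.05 * fs), 1)
    for _ in range(n_art):
        ch = rng.integers(n_ch)
        start = rng.integers(0, max(n - width, 1))
        data[ch, start:start + width] += amp * rng.choice((-1.0, 1.0))


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Bundle returned by :func:`synth_cohort`.

    ``true_features`` holds per subject x session the generator-side
    (noise-free) affected/healthy band-fraction draws and the realized
    complexity level, for generator-vs-analyzer consistency checks.
    """

    spec: CohortSpec
    subjects: list[SubjectRecord]
    recordings: list[EEGRecording]
    true_features: "object"  # pandas DataFrame; import kept lazy

    def recording(self, subject_id: str, session: str) -> EEGRecording:
        for r in self.recordings:
            if r.subject_id == subject_id and r.session == session:
                return r
        raise KeyError((subject_id, session))


def synth_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full two-group, two-session cohort.

    Fully deterministic given ``spec`` (per-subject RNG streams are keyed by
    ``(seed, subject_index)``, so enlarging the cohort leaves existing
    subjects' data unchanged).
    """
    import pandas as pd

    n = spec.n_per_group
    sides = ("left", "right")
    subjects: list[SubjectRecord] = []
    recordings: list[EEGRecording] = []
    rows = []
    feature_by_subject = {}

    for i in range(2 * n):
        group = "experimental" if i < n else "control"
        sid = f"s{i + 1:03d}"
        rng = default_rng(SeedSequence([int(spec.seed) & 0x7FFFFFFF, i]))
        side = sides[int(rng.integers(2))]
        age = int(rng.integers(40, 81))
        sex = "F" if rng.integers(2) else "M"
        nm = spec.nihss_model
        nihss_t0 = int(np.clip(int(round(
            rng.normal(nm.t0_mean[group], nm.t0_sd[group]))), 5, 20))
        nihss_eps = float(rng.standard_normal())  # reserved for NIHSS link
        affected = set(
            ("C3", "P3", "O1") if side == "left" else ("C4", "P4", "O2"))

        session_data = {}
        for sess in ("T0", "T1"):
            conc = spec.dirichlet_concentration
            targets = {
                hemi: np.asarray(
                    spec.band_fractions[(group, sess, hemi)], dtype=float)
                for hemi in ("affected", "healthy")
            }
            fracs = {
                hemi: rng.dirichlet(conc * targets[hemi])
                for hemi in ("affected", "healthy")
            }
            # Undo the common-average-reference mixing: with 6 channels of
            # equal power (3 per hemisphere, incoherent), re-referencing
            # turns per-channel band fractions g into (27 g_own + 3
            # g_other)/30, so synthesize with the inverse warp and the
            # measured fractions land on the drawn ones.
            synth_fracs = {}
            for hemi, other in (("affected", "healthy"),
                                ("healthy", "affected")):
                g = 1.125 * fracs[hemi] - 0.125 * fracs[other]
                g = np.clip(g, 1e-6, None)
                synth_fracs[hemi] = g / g.sum()
            c_nom = spec.complexity_level[(group, sess)]
            c = float(np.clip(
                c_nom + spec.complexity_jitter_sd * rng.standard_normal(),
                0.0, 1.0))
            data = np.empty(
                (len(REQUIRED_CHANNELS), int(round(spec.duration_s * spec.fs))))
            for ci, ch in enumerate(REQUIRED_CHANNELS):
                hemi = "affected" if ch in affected else "healthy"
                # distinct oscillation frequency per channel: orthogonal
                # across channels, so the average reference mixes power
                # deterministically
                offset = (ci - (len(REQUIRED_CHANNELS) - 1) / 2) * 0.2
                data[ci] = spec.signal_rms_uv * synth_signal(
                    synth_fracs[hemi], c, spec.duration_s, spec.fs, rng,
                    compensate=spec.compensate, osc_offset_hz=offset)
            if spec.artifact_rate > 0:
                _inject_artifacts(data, spec.artifact_rate,
                                  spec.artifact_amp_uv, spec.fs, rng)
            session_data[sess] = data
            af = fracs["affected"]
            rows.append({
                "subject_id": sid, "session": sess, "group": group,
                "infarct_side": side,
                "true_delta": af[0], "true_theta": af[1],
                "true_alpha": af[2], "true_beta": af[3],
                "true_complexity": c,
            })
            if sess == "T1":
                feature_by_subject[sid] = af[2] / af[3]

        subjects.append((sid, group, side, age, sex, nihss_t0, nihss_eps,
                         session_data))

    # NIHSS linkage: per group, centre the designated feature and set the
    # slope/noise to achieve the target correlation and dNIHSS moments.
    # Integer rounding and the nihss_t1 >= 0 clip attenuate the realized
    # correlation and shift the realized mean, so the design correlation
    # and intercept are tuned iteratively against the realized values.
    model = spec.nihss_model
    final_subjects = []
    for group in ("experimental", "control"):
        members = [s for s in subjects if s[1] == group]
        feats = np.array([feature_by_subject[s[0]] for s in members])
        eps = np.array([s[6] for s in members])
        t0s = np.array([s[5] for s in members])
        f_sd = feats.std()
        fc = feats - feats.mean()
        if model.slope is not None:
            intercept = model.intercept if model.intercept is not None else 0.0
            noise_sd = model.noise_sd if model.noise_sd is not None else 0.0
            deltas = intercept + model.slope * feats + noise_sd * eps
            t1s = np.maximum(np.rint(t0s - deltas), 0).astype(int)
        else:
            mu = model.delta_mean[group]
            sd = model.delta_sd[group]
            mu_adj, r_d = mu, model.target_corr
            t1s = np.rint(t0s - mu).astype(int)
            for _ in range(6):
                slope = (r_d * sd / f_sd) if f_sd > 0 else 0.0
                noise_sd = sd * np.sqrt(max(1.0 - r_d * r_d, 0.0))
                deltas = mu_adj + slope * fc + noise_sd * eps
                t1s = np.maximum(np.rint(t0s - deltas), 0).astype(int)
                realized = (t0s - t1s).astype(float)
                mu_adj += mu - realized.mean()
                if f_sd > 0 and realized.std() > 0 and abs(r_d) > 1e-9:
                    r_real = float(np.corrcoef(feats, realized)[0, 1])
                    if abs(r_real) > 0.05:
                        r_d = float(np.clip(
                            r_d * model.target_corr / r_real, -0.98, 0.98))
        for (sid, g, side, age, sex, t0, _eps, data), t1 in zip(members, t1s):
            rec = SubjectRecord(sid, g, side, age, sex, t0, int(t1))
            final_subjects.append(rec)
            for sess in ("T0", "T1"):
                recordings.append(EEGRecording(
                    sid, sess, spec.fs, REQUIRED_CHANNELS, data[sess]))

    final_subjects.sort(key=lambda r: r.subject_id)
    recordings.sort(key=lambda r: (r.subject_id, r.session))
    truth = pd.DataFrame(rows).sort_values(
        ["subject_id", "session"]).reset_index(drop=True)
    return SyntheticCohort(spec, final_subjects, recordings, truth)


def write_cohort(cohort: SyntheticCohort, out_dir, fmt: str = "edf") -> Path:
    """Write a cohort to disk: one file per subject x session + cohort.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        stem = out_dir / f"{rec.subject_id}_{rec.session}"
        if fmt == "edf":
            write_edf(rec, stem.with_suffix(".edf"))
        elif fmt == "array":
            from .io import write_array
            write_array(rec, stem)
        else:
            raise ValidationError(f"unknown format {fmt!r}")
    write_cohort_csv(cohort.subjects, out_dir / "cohort.csv")
    return out_dir
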