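"""Synthetic multichannel EEG with controllable functional connectivity.

The generator emulates 19-channel, 500 Hz resting-state EEG in which the
ground-truth coupling structure is known per group, per band and per
channel pair, so that every downstream stage (band filtering, phase /
envelope connectivity, thresholding, classification) can be verified
against construction.

Signal model, per frequency band ``b`` and channel ``i``::

    x_bi(t) = A_bi * e_bi(t) * cos(2*pi*f_b*t + theta0_i + w_bi(t))

* ``w_bi`` is stationary band-limited Gaussian phase wander, correlated
  across channels according to the phase-coupling template ``kappa``
  through the mixture law of a shared-driver construction (latent
  correlation ``2*kappa - kappa**2``, the variance law of
  ``(1-kappa)*own_noise + kappa*driver``).  ``kappa = 1`` makes two
  channels' wander identical (strict phase locking, zero lag);
  ``kappa = 0`` leaves their phase difference wandering over several
  radians, so the measured phase synchronization index decays toward a
  small stationary bias as O(1/sqrt(T)).  The initial phase of each band
  is shared across channels, so coupling is zero-lag: Pearson
  correlation sees shared drivers while the imaginary part of coherency,
  by design, does not.  Mixing independent noise through a Cholesky-type
  factor is a linear shared-driver mixture: each channel's wander is a
  weighted sum of independent latent drivers.
* ``e_bi`` is a slow (< 1 Hz) positive amplitude modulator: unit-variance
  Gaussian latents are correlated across channels via the Cholesky factor
  of the envelope template ``rho``, low-pass filtered, then passed through
  a softplus so envelopes stay positive.  The softplus is operated in its
  near-linear regime, so the measured amplitude-envelope correlation
  tracks ``rho`` closely but not exactly (acceptance bands, not
  equalities, are the contract).

Bands are summed with per-band amplitude scales and a white-noise floor
is added.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BandSpec, RHYTHM_BANDS
from .layout import ChannelLayout, DEFAULT_LABELS, default_layout, generic_layout

GROUPS = ("AD", "FTD", "HC")

#: Narrowband carrier frequency per rhythm band (Hz), at band centers
#: except delta (kept away from the 0.5 Hz broadband edge).
CARRIER_HZ = {"delta": 2.25, "theta": 6.0, "alpha": 10.0, "beta": 21.0, "low_gamma": 37.5}

#: Per-band amplitude scale (arbitrary units).  Eyes-closed resting EEG is
#: alpha-dominant with modest delta/theta and weak fast activity.
BAND_AMPLITUDE = {"delta": 0.6, "theta": 0.7, "alpha": 1.0, "beta": 0.5, "low_gamma": 0.3}

#: Baseline pairwise coupling for the non-degenerate bands.
BASELINE_KAPPA = 0.2
BASELINE_RHO = 0.2

#: The delta band is deliberately near-degenerate (almost uniform, very
#: strong coupling on every pair) so delta connectivity matrices carry no
#: group information, as observed for the real recordings.
DELTA_KAPPA = 0.95
DELTA_RHO = 0.95

#: Stationary per-channel phase-wander variance, rad^2.  The phase noise
#: is a zero-mean band-limited Gaussian process, so a pair with coupling
#: kappa has a stationary phase-difference variance 2*sigma^2*(1-C(kappa))
#: and an expected phasor magnitude exp(-sigma^2*(1-C)); at kappa = 0 the
#: wrapped difference is nearly uniform (PSI bias e^{-sigma^2} ~ 0.02)
#: and the measured PSI decays toward it as O(1/sqrt(T)).
PHASE_WANDER_VAR = 4.0

#: Band limit of the phase wander (Hz).  Keeps the FM sidebands inside
#: each rhythm band and the instantaneous frequency smooth; it also sets
#: the phase-decorrelation time (~1/cutoff) through which uncoupled
#: pairs lose zero-lag alignment within an epoch.
PHASE_NOISE_CUTOFF_HZ = 0.6

#: Low-pass cutoff of the envelope modulators (Hz); envelopes are slow
#: relative to every carrier.
ENVELOPE_CUTOFF_HZ = 0.7

_EFFECT_BANDS = ("theta", "alpha", "beta", "low_gamma")


@dataclass(frozen=True)
class CouplingTemplate:
    """Ground-truth coupling structure for one group and one band."""

    group: str
    band: str
    phase_coupling: np.ndarray      # kappa, channels x channels, in [0, 1]
    envelope_coupling: np.ndarray   # rho, channels x channels, in [-1, 1]
    amplitude_scale: np.ndarray     # per-channel positive gain
    noise_sd: float

    def __post_init__(self) -> None:
        k, r = self.phase_coupling, self.envelope_coupling
        for name, m in (("phase_coupling", k), ("envelope_coupling", r)):
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError(f"{name} diagonal must be 1")
        if k.min() < 0 or k.max() > 1:
            raise ValueError("phase coupling kappa must lie in [0, 1]")
        if r.min() < -1 or r.max() > 1:
            raise ValueError("envelope coupling rho must lie in [-1, 1]")
        if np.any(self.amplitude_scale <= 0):
            raise ValueError("amplitude_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.phase_coupling.shape[0]


@dataclass(frozen=True)
class Recording:
    """A labelled multichannel recording (channels x samples)."""

    data: np.ndarray
    fs: float
    layout: ChannelLayout
    group_label: str
    subject_id: str
    seed: int

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError("data row count must equal layout channel count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SyntheticDataset:
    """Recordings plus a manifest describing them."""

    recordings: tuple[Recording, ...]
    manifest: pd.DataFrame
    epoch_duration_s: float = 10.0


def _block_pairs(layout: ChannelLayout, regions_a: tuple[str, ...],
                 regions_b: tuple[str, ...]) -> np.ndarray:
    """Boolean mask of cross-region channel pairs (symmetric, zero diag)."""
    n = layout.n_channels
    a = np.zeros(n, dtype=bool)
    b = np.zeros(n, dtype=bool)
    for r in regions_a:
        a[layout.channels_in_region(r)] = True
    for r in regions_b:
        b[layout.channels_in_region(r)] = True
    mask = np.outer(a, b) | np.outer(b, a)
    np.fill_diagonal(mask, False)
    return mask


def discriminative_masks(layout: ChannelLayout) -> dict[str, np.ndarray]:
    """Channel-pair masks on which each patient-like group is elevated.

    The FTD-like group is elevated on frontal-temporal pairs; the AD-like
    group on a disjoint posterior (parietal/occipital) block.
    """
    ftd = _block_pairs(layout, ("frontal",), ("temporal",))
    post = np.array([layout.region_map[l] in ("parietal", "occipital")
                     for l in layout.labels])
    ad = np.outer(post, post)
    np.fill_diagonal(ad, False)
    if (ftd & ad).any():
        raise ValueError("discriminative blocks must be disjoint")
    return {"FTD": ftd, "AD": ad}


def make_group_templates(
    effect_size: float,
    layout: ChannelLayout | None = None,
    seed: int = 0,
    *,
    baseline_kappa: float = BASELINE_KAPPA,
    baseline_rho: float = BASELINE_RHO,
) -> dict[str, dict[str, CouplingTemplate]]:
    """Build per-group, per-band coupling templates.

    All three groups share a baseline; the FTD-like group has ``kappa`` and
    ``rho`` elevated by ``effect_size`` on frontal-temporal pairs, and the
    AD-like group on a disjoint posterior block, in every rhythm band
    except delta (which is near-degenerate for every group by design).
    ``effect_size = 0`` yields three identical template sets.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be nonnegative")
    layout = layout or default_layout()
    n = layout.n_channels
    masks = discriminative_masks(layout)

    for base in (baseline_kappa, baseline_rho):
        if not (0 <= base <= 1):
            raise ValueError("baseline coupling must lie in [0, 1]")
    if baseline_kappa + effect_size > 1 or baseline_rho + effect_size > 1:
        raise ValueError(
            f"effect_size {effect_size} pushes coupling past 1 "
            f"(baselines kappa={baseline_kappa}, rho={baseline_rho})"
        )

    templates: dict[str, dict[str, CouplingTemplate]] = {}
    mean_amp = float(np.mean(list(BAND_AMPLITUDE.values())))
    noise_sd = 0.1 * mean_amp
    for group in GROUPS:
        per_band: dict[str, CouplingTemplate] = {}
        for band in RHYTHM_BANDS:
            if band.name == "delta":
                k0, r0 = DELTA_KAPPA, DELTA_RHO
            else:
                k0, r0 = baseline_kappa, baseline_rho
            kappa = np.full((n, n), k0)
            rho = np.full((n, n), r0)
            np.fill_diagonal(kappa, 1.0)
            np.fill_diagonal(rho, 1.0)
            if band.name in _EFFECT_BANDS and group in masks:
                kappa[masks[group]] += effect_size
                rho[masks[group]] += effect_size
            per_band[band.name] = CouplingTemplate(
                group=group,
                band=band.name,
                phase_coupling=kappa,
                envelope_coupling=rho,
                amplitude_scale=np.full(n, BAND_AMPLITUDE[band.name]),
                noise_sd=noise_sd,
            )
        templates[group] = per_band
    return templates


def _nearest_correlation_factor(c: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a correlation matrix, eigenvalue-clipped
    for numerical positive-semidefiniteness.  Clipping at exactly zero
    keeps fully-coupled channels bit-identical after factorization."""
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 0.0, None)
    f = v * np.sqrt(w)
    # renormalize rows so marginals keep unit variance
    norms = np.sqrt((f ** 2).sum(axis=1))
    return f / norms[:, None]


#: Sampling rate (Hz) at which the slow latent processes are generated
#: before linear interpolation to the signal rate.  All latents are
#: band-limited well below 1 Hz, so 25 Hz leaves interpolation error in
#: the fourth decimal while cutting generation cost by more than an
#: order of magnitude.
_SLOW_FS = 25.0


def _slow_gaussian(mix_factor: np.ndarray, n_samples: int, fs: float,
                   cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Cross-correlated, low-pass-filtered, unit-variance Gaussian latents
    at the signal rate (generated at a low rate, linearly interpolated)."""
    n = mix_factor.shape[0]
    n_slow = int(np.ceil(n_samples * _SLOW_FS / fs)) + 2
    z = rng.standard_normal((n, n_slow), dtype=np.float32)
    g = mix_factor.astype(np.float32) @ z
    sos = signal.butter(2, cutoff_hz, btype="low", fs=_SLOW_FS, output="sos")
    g = signal.sosfiltfilt(sos, g, axis=1).astype(np.float32)
    pos = np.arange(n_samples, dtype=np.float64) * (_SLOW_FS / fs)
    idx = pos.astype(np.intp)
    frac = (pos - idx).astype(np.float32)
    out = g[:, idx] * (1 - frac) + g[:, idx + 1] * frac
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    out /= sd
    return out


def _slow_modulators(rho: np.ndarray, n_samples: int, fs: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Positive, slow envelope modulators with target pairwise correlation.

    float32 throughout: the modulators are smooth and O(1), so single
    precision is ample.
    """
    f = _nearest_correlation_factor(rho)
    g = _slow_gaussian(f, n_samples, fs, ENVELOPE_CUTOFF_HZ, rng)
    # softplus around 1.5 is close to linear, keeps envelopes positive
    x = np.float32(1.5) + np.float32(0.5) * g
    return np.logaddexp(np.float32(0.0), x)


def _band_signal(template: CouplingTemplate, band: BandSpec, n_samples: int,
                 fs: float, rng: np.random.Generator) -> np.ndarray:
    n = template.n_channels
    f_c = CARRIER_HZ[band.name]
    # the mixture phi = (1-kappa)*noise + kappa*driver gives a pairwise
    # phase-difference variance proportional to (1-kappa)^2, i.e. a
    # latent correlation of 2*kappa - kappa^2
    kappa = template.phase_coupling
    corr = 2 * kappa - kappa ** 2
    factor = _nearest_correlation_factor(corr)
    wander = _slow_gaussian(factor, n_samples, fs, PHASE_NOISE_CUTOFF_HZ, rng)
    wander *= np.float32(np.sqrt(PHASE_WANDER_VAR))
    t = np.arange(n_samples) / fs
    # one shared initial phase per band: coupling is zero-lag (the
    # volume-conduction-like regime where Corr sees shared drivers and
    # ImCoh, by design, does not); uncoupled channels still diverge
    # within a decorrelation time through their independent phase noise
    theta0 = np.float32(rng.uniform(0, 2 * np.pi))
    # the deterministic carrier ramp is identical across channels, so its
    # float32 rounding is common mode and cancels in phase differences
    phase = (2 * np.pi * f_c * t)[None, :].astype(np.float32) \
        + theta0 + wander
    env = _slow_modulators(template.envelope_coupling, n_samples, fs, rng)
    return template.amplitude_scale[:, None].astype(np.float32) * env * np.cos(phase)


def simulate_recording(
    templates: dict[str, CouplingTemplate],
    duration_s: float,
    fs: float = 500.0,
    seed: int = 0,
    *,
    layout: ChannelLayout | None = None,
    group_label: str | None = None,
    subject_id: str = "S000",
) -> Recording:
    """Simulate one multichannel recording from per-band templates.

    ``templates`` maps band name -> :class:`CouplingTemplate` (one group's
    set, as produced by :func:`make_group_templates`).
    """
    if duration_s < 10:
        raise ValueError("duration_s must be at least one 10 s epoch")
    if layout is None:
        n_ch = next(iter(templates.values())).n_channels
        layout = default_layout() if n_ch == len(DEFAULT_LABELS) else generic_layout(n_ch)
    bands = [b for b in RHYTHM_BANDS if b.name in templates]
    if not bands:
        raise ValueError("templates must cover at least one rhythm band")
    max_edge = max(b.high_hz for b in bands)
    if fs < 2 * max_edge:
        raise ValueError(
            f"fs={fs} Hz aliases the {max_edge} Hz band edge (need >= {2 * max_edge})"
        )

    n_samples = int(round(duration_s * fs))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(bands) + 1)
    data = np.zeros((layout.n_channels, n_samples), dtype=np.float32)
    for band, child in zip(bands, children[:-1]):
        data += _band_signal(templates[band.name], band, n_samples, fs,
                             np.random.default_rng(child))
    noise_sd = templates[bands[0].name].noise_sd
    if noise_sd > 0:
        noise = np.random.default_rng(children[-1]).standard_normal(
            data.shape, dtype=np.float32)
        data += np.float32(noise_sd) * noise
    group = group_label or templates[bands[0].name].group
    return Recording(
        data=data.astype(np.float32),
        fs=fs,
        layout=layout,
        group_label=group,
        subject_id=subject_id,
        seed=seed,
    )


def subject_seed(master_seed: int, subject_index: int) -> int:
    """Counter-based per-subject seed derivation from one master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(subject_index,))
    return int(ss.generate_state(1)[0])


def simulate_dataset(
    n_subjects_per_group: int,
    epochs_per_subject: int,
    effect_size: float,
    seed: int = 0,
    *,
    layout: ChannelLayout | None = None,
    fs: float = 500.0,
    epoch_duration_s: float = 10.0,
    with_severity: bool = False,
) -> SyntheticDataset:
    """Simulate a labelled three-group dataset plus its manifest.

    Each of the ``3 * n_subjects_per_group`` subjects gets one recording
    exactly long enough for ``epochs_per_subject`` non-overlapping epochs.
    With ``with_severity`` each patient-like subject's discriminative
    coupling elevation is scaled by a per-subject severity multiplier
    drawn uniformly from [0.5, 1.5] (HC-like subjects get severity 0).
    """
    if n_subjects_per_group < 1 or epochs_per_subject < 1:
        raise ValueError("subject and epoch counts must be >= 1")
    layout = layout or default_layout()
    duration = epochs_per_subject * epoch_duration_s
    base_templates = make_group_templates(effect_size, layout)

    recordings: list[Recording] = []
    rows = []
    idx = 0
    for group in GROUPS:
        for j in range(n_subjects_per_group):
            sid = f"{group}{j:03d}"
            s = subject_seed(seed, idx)
            severity = np.nan
            templates = base_templates[group]
            if with_severity:
                if group == "HC":
                    severity = 0.0
                else:
                    sev_rng = np.random.default_rng(
                        np.random.SeedSequence(seed, spawn_key=(idx, 1))
                    )
                    severity = float(sev_rng.uniform(0.5, 1.5))
                    templates = make_group_templates(
                        effect_size * severity, layout
                    )[group]
            rec = simulate_recording(
                templates, duration, fs, s,
                layout=layout, group_label=group, subject_id=sid,
            )
            recordings.append(rec)
            rows.append({
                "subject_id": sid, "group": group, "seed": s,
                "n_epochs": epochs_per_subject, "severity": severity,
            })
            idx += 1
    manifest = pd.DataFrame(rows)
    return SyntheticDataset(tuple(recordings), manifest, epoch_duration_s)


def single_pair_templates(
    n_channels: int,
    pair: tuple[int, int],
    kappa: float = 0.0,
    rho: float = 0.0,
    *,
    bands: tuple[str, ...] = ("alpha",),
    baseline_kappa: float = 0.0,
    baseline_rho: float = 0.0,
    noise_sd: float = 0.0,
) -> dict[str, CouplingTemplate]:
    """Templates with coupling on exactly one channel pair — a convenience
    for calibration and ground-truth tests."""
    i, j = pair
    per_band = {}
    for name in bands:
        k = np.full((n_channels, n_channels), baseline_kappa)
        r = np.full((n_channels, n_channels), baseline_rho)
        np.fill_diagonal(k, 1.0)
        np.fill_diagonal(r, 1.0)
        k[i, j] = k[j, i] = kappa
        r[i, j] = r[j, i] = rho
        per_band[name] = CouplingTemplate(
            group="HC", band=name, phase_coupling=k, envelope_coupling=r,
            amplitude_scale=np.ones(n_channels), noise_sd=noise_sd,
        )
    return per_band
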