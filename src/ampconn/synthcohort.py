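"""Synthetic two-group cohorts of ROI-level oscillatory epochs.

The generator emulates the inputs of a staged overt-naming experiment:
per-subject multi-trial band-limited oscillatory epochs (default -200..600 ms
at 600 Hz) on a refined cortical parcellation, with

- a planted phase-locking network: regions in the same functional module
  share a per-trial driver phase and deviate from it by von Mises jitter with
  per-region concentration ``kappa``, so that the asymptotic PLV of a
  same-module pair is ``R(kappa_i) * R(kappa_j)`` with
  ``R(k) = I_1(k) / I_0(k)`` (mean resultant length of the von Mises
  distribution);
- a planted node-amplitude field carried by a slow evoked offset that
  survives trial averaging, while the oscillatory carrier has a uniform
  per-trial driver phase and therefore cancels in the trial average;
- a controllable per-group sign and strength of the correlation between the
  planted amplitude field and the planted connectivity strength, induced by
  construction (the amplitude score is an exact linear blend of the
  standardized planted strength and an orthogonalized noise vector).

Amplitude and connectivity fields are drawn independently for every subject:
under a zero planted correlation all subjects are exchangeable, which is the
null the downstream 5-vs-5 group-permutation test assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "ConfigurationError",
    "SynthConfig",
    "EpochSet",
    "RoiAtlas",
    "GroundTruth",
    "FUNCTIONAL_SYSTEMS",
    "STAGE_WINDOWS",
    "BASELINE_WINDOW",
    "make_atlas",
    "plv_from_kappa",
    "kappa_from_plv",
    "generate_cohort",
    "generate_phase_epochs",
    "table1_fixture",
    "stage_windows_fixture",
    "window_slice",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


#: The eight functional systems; split by hemisphere they give 16 modules.
FUNCTIONAL_SYSTEMS: Tuple[str, ...] = (
    "frontoparietal",
    "medial_default_mode",
    "visual",
    "ventral_temporal_association",
    "attention",
    "cingulo_opercular",
    "motor_somatosensory",
    "auditory",
)

#: Naming-stage windows in ms after picture onset (half-open [start, end)).
STAGE_WINDOWS: Tuple[Tuple[str, float, float], ...] = (
    ("t1", 0.0, 119.0),
    ("t2", 120.0, 150.0),
    ("t3", 151.0, 190.0),
    ("t4", 191.0, 320.0),
    ("t5", 321.0, 480.0),
    ("t6", 481.0, 535.0),
)

BASELINE_WINDOW: Tuple[float, float] = (-200.0, 0.0)

GROUPS: Tuple[str, str] = ("broca", "control")


def stage_windows_fixture() -> List[Tuple[str, float, float]]:
    """Stage windows of the naming task plus the pre-stimulus baseline."""
    return list(STAGE_WINDOWS) + [("baseline", *BASELINE_WINDOW)]


def window_slice(start_ms: float, end_ms: float, t0_ms: float, sfreq: float) -> slice:
    """Map a half-open ms window [start, end) to epoch sample indices.

    A time point ``t`` (ms) maps to sample ``floor((t - t0) * sfreq / 1000)``.
    """
    lo = math.floor((start_ms - t0_ms) * sfreq / 1000.0)
    hi = math.floor((end_ms - t0_ms) * sfreq / 1000.0)
    return slice(lo, hi)


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_subjects_per_group:
        Matched group sizes (5 vs 5 in the emulated study design).
    n_roi:
        Number of refined ROIs; must be divisible by 6 (each original ROI is
        subdivided into six refined children).
    n_modules:
        Number of functional modules partitioning the ROIs (16 = 8 systems
        split by hemisphere).
    n_trials:
        Correct-response trials per subject.
    sfreq:
        Sampling rate in Hz.
    epoch_window:
        Epoch limits in ms relative to stimulus onset; must contain 0.
    band:
        Pass band in Hz for the oscillatory carrier (gamma 30-45 Hz).
    coupling_rho:
        Per-group target Pearson correlation between the planted node
        amplitude and the planted node strength, each in [-1, 1].
    kappa_range:
        Range of per-ROI von Mises phase concentrations (>= 0).
    amp_range:
        Range of planted task amplitudes, picoampere scale (positive).
    baseline_kappa:
        Phase concentration during the pre-stimulus baseline (weak coupling
        so baseline normalization is meaningful).
    baseline_amp:
        Evoked offset during the baseline segment (pA).
    carrier_amp:
        Amplitude of the oscillatory carrier (pA).
    noise_sd:
        Additive white-noise standard deviation (pA).
    seed:
        Seed of the cohort-level random stream.
    """

    n_subjects_per_group: int = 5
    n_roi: int = 120
    n_modules: int = 16
    n_trials: int = 60
    sfreq: float = 600.0
    epoch_window: Tuple[float, float] = (-200.0, 600.0)
    band: Tuple[float, float] = (30.0, 45.0)
    coupling_rho: Mapping[str, float] = field(
        default_factory=lambda: {"broca": 0.5, "control": -0.5}
    )
    kappa_range: Tuple[float, float] = (0.5, 8.0)
    amp_range: Tuple[float, float] = (5.0, 50.0)
    baseline_kappa: float = 0.3
    baseline_amp: float = 10.0
    carrier_amp: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ConfigurationError("n_subjects_per_group must be >= 1")
        if self.n_roi < 6 or self.n_roi % 6 != 0:
            raise ConfigurationError("n_roi must be a positive multiple of 6")
        if self.n_modules < 1 or self.n_modules > self.n_roi // 6:
            raise ConfigurationError(
                "n_modules must be between 1 and the number of original ROIs"
            )
        if self.n_trials < 2:
            raise ConfigurationError("n_trials must be >= 2 (PLV needs >= 2 trials)")
        if self.sfreq <= 0:
            raise ConfigurationError("sfreq must be positive")
        lo, hi = self.epoch_window
        if not (lo < 0.0 <= hi):
            raise ConfigurationError("epoch_window must contain 0")
        b0, b1 = self.band
        if not (0.0 < b0 < b1 < self.sfreq / 2.0):
            raise ConfigurationError("band must satisfy 0 < low < high < sfreq/2")
        if isinstance(self.coupling_rho, (tuple, list)):
            self.coupling_rho = dict(zip(GROUPS, self.coupling_rho))
        for g, rho in self.coupling_rho.items():
            if not -1.0 <= rho <= 1.0:
                raise ConfigurationError(f"coupling_rho[{g!r}] must lie in [-1, 1]")
        k0, k1 = self.kappa_range
        if k0 < 0 or k1 < k0:
            raise ConfigurationError("kappa_range must be an increasing pair with low >= 0")
        a0, a1 = self.amp_range
        if a0 <= 0 or a1 < a0:
            raise ConfigurationError("amp_range must be an increasing positive pair")
        if self.baseline_kappa < 0:
            raise ConfigurationError("baseline_kappa must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        lo, hi = self.epoch_window
        return int(round((hi - lo) * self.sfreq / 1000.0))


@dataclass
class EpochSet:
    """Per-subject epoched ROI time series (trials x ROI x samples, pA scale)."""

    subject_id: str
    group: str
    data: np.ndarray
    sfreq: float
    t0_ms: float
    roi_labels: List[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x roi x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")
        if self.data.shape[1] != len(self.roi_labels):
            raise ValueError("roi_labels length must match the ROI axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.sfreq

    def window(self, start_ms: float, end_ms: float) -> slice:
        return window_slice(start_ms, end_ms, self.t0_ms, self.sfreq)


@dataclass
class RoiAtlas:
    """Mapping of refined ROIs to original ROIs, hemispheres and modules."""

    frame: pd.DataFrame  # columns: refined_id, original_id, hemisphere, module

    REQUIRED = ("refined_id", "original_id", "hemisphere", "module")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"atlas is missing columns: {missing}")
        if self.frame["refined_id"].duplicated().any():
            raise ValueError("refined_id values must be unique")

    @property
    def refined_ids(self) -> List[str]:
        return list(self.frame["refined_id"])

    @property
    def n_modules(self) -> int:
        return int(self.frame["module"].nunique())

    def module_of(self) -> Dict[str, int]:
        return dict(zip(self.frame["refined_id"], self.frame["module"].astype(int)))

    def original_of(self) -> Dict[str, str]:
        return dict(zip(self.frame["refined_id"], self.frame["original_id"]))

    def module_names(self) -> Dict[int, str]:
        if "module_name" in self.frame.columns:
            return dict(
                zip(self.frame["module"].astype(int), self.frame["module_name"])
            )
        return {m: f"module{m}" for m in sorted(self.frame["module"].unique())}

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RoiAtlas":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort (for parameter-recovery tests).

    Per-subject fields are keyed by subject id; ``planted_rho`` is per group.
    """

    planted_plv: Dict[str, np.ndarray]
    planted_amplitude: Dict[str, np.ndarray]
    kappa: Dict[str, np.ndarray]
    planted_rho: Dict[str, float]
    hub_set: Dict[str, List[int]]

    def planted_strength(self, subject_id: str) -> np.ndarray:
        return self.planted_plv[subject_id].sum(axis=1)


# ---------------------------------------------------------------------------
# von Mises phase concentration <-> PLV
# ---------------------------------------------------------------------------


def plv_from_kappa(kappa) -> np.ndarray:
    """Mean resultant length R(kappa) = I1(kappa)/I0(kappa) of a von Mises law."""
    kappa = np.asarray(kappa, dtype=float)
    out = np.ones_like(kappa)
    finite = np.isfinite(kappa)
    # exponentially scaled Bessel ratio is stable for large kappa
    out[finite] = special.i1e(kappa[finite]) / special.i0e(kappa[finite])
    return out if out.ndim else float(out)


def kappa_from_plv(r: float) -> float:
    """Invert ``plv_from_kappa`` numerically; r in [0, 1)."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("target mean resultant length must lie in [0, 1]")
    if r == 0.0:
        return 0.0
    if r >= 0.9999:
        return math.inf
    return float(optimize.brentq(lambda k: plv_from_kappa(k) - r, 1e-8, 1e4))


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


def make_atlas(n_roi: int, n_modules: int) -> RoiAtlas:
    """Build a synthetic refined-ROI atlas with an exact 6:1 subdivision.

    Original ROIs are assigned round-robin to modules; all six refined
    children of an original inherit its module and hemisphere.  With an even
    module count, modules come in hemisphere pairs (2s+1 left, 2s+2 right for
    system s), mirroring an 8-system x 2-hemisphere scheme at n_modules=16.
    """
    if n_roi % 6 != 0:
        raise ConfigurationError("n_roi must be a multiple of 6")
    n_original = n_roi // 6
    if n_modules > n_original:
        raise ConfigurationError("n_modules cannot exceed the number of original ROIs")
    rows = []
    for o in range(n_original):
        module = (o % n_modules) + 1
        if n_modules % 2 == 0:
            system_idx = (module - 1) // 2
            hemi = "L" if (module - 1) % 2 == 0 else "R"
        else:
            system_idx = module - 1
            hemi = "L" if o < n_original / 2 else "R"
        if system_idx < len(FUNCTIONAL_SYSTEMS):
            name = f"{FUNCTIONAL_SYSTEMS[system_idx]}_{hemi}"
        else:
            name = f"system{system_idx + 1}_{hemi}"
        for c in range(6):
            r = o * 6 + c
            rows.append(
                {
                    "refined_id": f"r{r:04d}",
                    "original_id": f"o{o:03d}",
                    "hemisphere": hemi,
                    "module": module,
                    "module_name": name,
                }
            )
    return RoiAtlas(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd < 1e-12:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _sample_von_mises(rng: np.random.Generator, kappa: np.ndarray, size) -> np.ndarray:
    """Von Mises(0, kappa) draws; kappa = inf yields exactly zero jitter."""
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), size[-1:])
    out = np.zeros(size)
    finite = np.isfinite(kappa)
    if finite.any():
        out[..., finite] = rng.vonmises(0.0, kappa[finite], size=size[:-1] + (int(finite.sum()),))
    return out


def _render_segment(
    rng: np.random.Generator,
    tau_s: np.ndarray,
    offsets: np.ndarray,
    kappa: np.ndarray,
    modules: np.ndarray,
    n_trials: int,
    f0: float,
    carrier_amp: float,
) -> np.ndarray:
    """One epoch segment: evoked offset + module-driver carrier with jitter."""
    n_roi = kappa.shape[0]
    n_modules = int(modules.max()) + 1
    theta = rng.uniform(-np.pi, np.pi, size=(n_trials, n_modules))
    eps = _sample_von_mises(rng, kappa, (n_trials, n_roi))
    phase0 = theta[:, modules] + eps  # (trials, roi)
    arg = 2.0 * np.pi * f0 * tau_s[None, None, :] + phase0[:, :, None]
    return offsets[None, :, None] + carrier_amp * np.cos(arg)


def _render_subject(
    rng: np.random.Generator,
    config: SynthConfig,
    modules: np.ndarray,
    kappa: np.ndarray,
    amplitude: np.ndarray,
) -> np.ndarray:
    n = config.n_samples
    tau_s = (config.epoch_window[0] + np.arange(n) * 1000.0 / config.sfreq) / 1000.0
    base = tau_s < 0.0
    f0 = 0.5 * (config.band[0] + config.band[1])
    data = np.empty((config.n_trials, config.n_roi, n))
    base_kappa = np.full(config.n_roi, config.baseline_kappa)
    base_amp = np.full(config.n_roi, config.baseline_amp)
    data[:, :, base] = _render_segment(
        rng, tau_s[base], base_amp, base_kappa, modules, config.n_trials, f0,
        config.carrier_amp,
    )
    data[:, :, ~base] = _render_segment(
        rng, tau_s[~base], amplitude, kappa, modules, config.n_trials, f0,
        config.carrier_amp,
    )
    if config.noise_sd > 0:
        data += config.noise_sd * rng.standard_normal(data.shape)
    return data


def _plant_fields(
    rng: np.random.Generator, config: SynthConfig, modules: np.ndarray, rho: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (kappa, planted PLV, amplitude) with an exact amplitude-strength r."""
    n = config.n_roi
    k_lo, k_hi = config.kappa_range
    u = rng.standard_normal(n)
    ranks = np.argsort(np.argsort(u))
    kappa = k_lo + (k_hi - k_lo) * ranks / max(n - 1, 1)
    resultant = np.asarray(plv_from_kappa(kappa))
    same_module = modules[:, None] == modules[None, :]
    plv = np.where(same_module, resultant[:, None] * resultant[None, :], 0.0)
    np.fill_diagonal(plv, 0.0)
    strength = plv.sum(axis=1)

    s_std = _standardize(strength)
    w = rng.standard_normal(n)
    if np.any(s_std):
        w = w - (w @ s_std) / (s_std @ s_std) * s_std
    w_std = _standardize(w)
    score = rho * s_std + math.sqrt(max(0.0, 1.0 - rho * rho)) * w_std
    a_lo, a_hi = config.amp_range
    amplitude = 0.5 * (a_lo + a_hi) + score * (a_hi - a_lo) / 6.0
    amplitude = np.clip(amplitude, 0.1 * a_lo, None)
    return kappa, plv, amplitude


def generate_cohort(
    config: SynthConfig,
) -> Tuple[List[EpochSet], RoiAtlas, GroundTruth]:
    """Generate a two-group synthetic cohort.

    Returns the per-subject epoch sets, the refined-ROI atlas and the planted
    ground truth.  Deterministic given ``config.seed``.
    """
    atlas = make_atlas(config.n_roi, config.n_modules)
    modules = atlas.frame["module"].to_numpy(dtype=int) - 1
    labels = atlas.refined_ids

    ss = np.random.SeedSequence(config.seed)
    epoch_sets: List[EpochSet] = []
    truth = GroundTruth({}, {}, {}, dict(config.coupling_rho), {})
    for g_idx, group in enumerate(GROUPS):
        rho = float(config.coupling_rho.get(group, 0.0))
        for s_idx in range(config.n_subjects_per_group):
            subject_id = f"{'B' if group == 'broca' else 'C'}{s_idx + 1}"
            rng = np.random.default_rng(ss.spawn(1)[0])
            kappa, plv, amplitude = _plant_fields(rng, config, modules, rho)
            data = _render_subject(rng, config, modules, kappa, amplitude)
            epoch_sets.append(
                EpochSet(
                    subject_id=subject_id,
                    group=group,
                    data=data,
                    sfreq=config.sfreq,
                    t0_ms=config.epoch_window[0],
                    roi_labels=labels,
                )
            )
            truth.planted_plv[subject_id] = plv
            truth.planted_amplitude[subject_id] = amplitude
            truth.kappa[subject_id] = kappa
            strength = plv.sum(axis=1)
            thr = amplitude.mean() + amplitude.std(ddof=1)
            k = int((amplitude > thr).sum())
            order = np.lexsort((np.arange(config.n_roi), -strength))
            truth.hub_set[subject_id] = sorted(order[:k].tolist())
    return epoch_sets, atlas, truth


def generate_phase_epochs(
    plv_target: np.ndarray,
    kappa_map: np.ndarray | None = None,
    n_trials: int = 60,
    sfreq: float = 600.0,
    window: Tuple[float, float] = (-200.0, 600.0),
    seed: int | None = None,
    band: Tuple[float, float] = (30.0, 45.0),
    carrier_amp: float = 1.0,
    noise_sd: float = 0.0,
    subject_id: str = "S1",
    group: str = "synthetic",
) -> EpochSet:
    """Render one EpochSet whose asymptotic PLV matrix matches ``plv_target``.

    ROIs connected in ``plv_target`` share a per-trial driver phase; the
    per-ROI von Mises concentration is either given via ``kappa_map`` or
    fitted from the target (log PLV_ij = log R_i + log R_j least squares per
    driver component).
    """
    plv_target = np.asarray(plv_target, dtype=float)
    if plv_target.ndim != 2 or plv_target.shape[0] != plv_target.shape[1]:
        raise ValueError("plv_target must be a square matrix")
    if not np.allclose(plv_target, plv_target.T, atol=1e-10):
        raise ValueError("plv_target must be symmetric")
    if plv_target.min() < 0 or plv_target.max() > 1:
        raise ValueError("plv_target entries must lie in [0, 1]")
    n = plv_target.shape[0]

    # driver components: connected components of the nonzero pattern
    adj = plv_target > 0
    modules = np.full(n, -1)
    comp = 0
    for start in range(n):
        if modules[start] >= 0:
            continue
        stack = [start]
        modules[start] = comp
        while stack:
            v = stack.pop()
            for u in np.nonzero(adj[v])[0]:
                if modules[u] < 0:
                    modules[u] = comp
                    stack.append(u)
        comp += 1

    if kappa_map is None:
        resultant = np.ones(n)
        off = plv_target.copy()
        np.fill_diagonal(off, 0.0)
        for c in range(comp):
            nodes = np.nonzero(modules == c)[0]
            edges = [
                (i, j)
                for ii, i in enumerate(nodes)
                for j in nodes[ii + 1 :]
                if off[i, j] > 0
            ]
            if not edges:
                resultant[nodes] = 0.0
                continue
            # least squares for log R_i on log plv_ij = log R_i + log R_j
            idx = {v: k for k, v in enumerate(nodes)}
            A = np.zeros((len(edges), len(nodes)))
            b = np.zeros(len(edges))
            for row, (i, j) in enumerate(edges):
                A[row, idx[i]] = 1.0
                A[row, idx[j]] = 1.0
                b[row] = math.log(off[i, j])
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            resultant[nodes] = np.minimum(np.exp(sol), 1.0)
        kappa = np.array([kappa_from_plv(min(r, 1.0)) for r in resultant])
    else:
        kappa = np.asarray(kappa_map, dtype=float)
        if kappa.shape != (n,):
            raise ValueError("kappa_map must have one entry per ROI")

    rng = np.random.default_rng(seed)
    n_samples = int(round((window[1] - window[0]) * sfreq / 1000.0))
    tau_s = (window[0] + np.arange(n_samples) * 1000.0 / sfreq) / 1000.0
    f0 = 0.5 * (band[0] + band[1])
    data = _render_segment(
        rng, tau_s, np.zeros(n), kappa, modules, n_trials, f0, carrier_amp
    )
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)
    return EpochSet(
        subject_id=subject_id,
        group=group,
        data=data,
        sfreq=sfreq,
        t0_ms=window[0],
        roi_labels=[f"r{i:04d}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# in-study fixtures
# ---------------------------------------------------------------------------

_TABLE1 = {
    "subject": ["B1", "B2", "B3", "B4", "B5", "C1", "C2", "C3", "C4", "C5"],
    "group": ["broca"] * 5 + ["control"] * 5,
    "pair_index": [1, 2, 3, 4, 5, 1, 2, 3, 4, 5],
    "gender": ["M", "M", "M", "M", "M", "F", "M", "M", "M", "M"],
    "age_years": [71, 50, 48, 55, 19, 68, 55, 55, 54, 70],
    "education_years": [7, 10, 10, 16, 9, 8, 8, 9, 12, 9],
    "months_post_onset": [8.0, 5.0, 5.0, 42.7, 9.4] + [float("nan")] * 5,
    "AQ": [31.4, 64.6, 43.8, 53.5, 58.3, 98.0, 99.4, 99.4, 99.6, 99.8],
    "spontaneous_speech": [6, 12, 8, 10, 12, 19, 20, 20, 20, 20],
    "auditory_comprehension": [90, 138, 154, 129, 133, 200, 194, 200, 198, 198],
    "repetition": [29, 70, 49, 64, 57, 100, 100, 97, 100, 100],
    "naming": [23, 54, 13, 39, 48, 100, 100, 100, 100, 100],
}


def table1_fixture() -> pd.DataFrame:
    """Demographics and WAB scores of the five matched pairs (verbatim)."""
    return pd.DataFrame(_TABLE1)
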