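"""Synthetic study generator: signals, cohort covariates, brainstem volumes.

No recordings are distributed with the analysis this package implements, so
every downstream stage is exercised against a generator that reproduces the
*statistical structure* the analysis assumes:

Signals
    Band-limited coupled phase oscillators (Kuramoto-Sakaguchi). Each
    frequency band hosts one oscillator network whose natural frequencies are
    uniform within the band. The coupling matrix switches among ``n_states``
    recurring modular templates with exponentially distributed dwell times
    (semi-Markov), which produces the recurring co-activation patterns that
    fluidity quantifies. A nonzero Sakaguchi phase-frustration angle makes
    synchronized modules lock with nonzero phase lags, so phase-lag-index
    connectivity (which ignores zero-lag coupling) sees the coupling too.
    The observed signal is the sum over bands of ``sin(phase)`` plus white
    Gaussian observation noise.

Cohort
    Group sizes, ages, sex, premorbid intelligence, cognitive-domain scores
    with configurable rank correlations to chosen connectivity features,
    clinical-scale scores with group offsets, and an LC contrast ratio tied to
    fluidity through a quadratic response whose slope/curvature can differ in
    the low-cognitive-reserve subgroup (the moderation downstream regression
    recovers). All links are generated on standardized variables; the median
    split itself happens downstream.

Volumes
    Neuromelanin-like intensity volumes: a uniform pontine-tegmentum
    reference level, locus-coeruleus cross plateaus with exactly planted
    contrast ratios per slice, optional fourth-ventricle signal void placed to
    trigger the extractor's shift rule, plus the search/reference masks.

Everything is deterministic under its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # jit-compiled integrator; pure-numpy fallback keeps results identical
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


from .lc_contrast import LCVolume
from .signals import BROADBAND, DEFAULT_BANDS, BandSpec, RegionTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "CohortConfig",
    "VolumeConfig",
    "simulate_subject_signals",
    "simulate_cohort",
    "simulate_nm_volume",
    "subject_seeds",
]

#: per-group, per-band coupling strengths used when none are configured:
#: the intermediate group is delta-hyperconnected relative to HC, the
#: impaired group falls back toward HC levels (the nonlinear trajectory the
#: analysis is designed to detect)
DEFAULT_COUPLING = {
    "HC": {"delta": 0.3},
    "CN-CCF": {"delta": 0.8},
    "MCI-LB": {"delta": 0.5},
}
_BASE_COUPLING = 0.4  # any (group, band) not listed above


@dataclass
class SimulationConfig:
    """Oscillator-network simulation settings for one subject's signals."""

    n_regions: int = 90
    fs: float = 250.0
    duration: float = 60.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    n_states: int = 3
    dwell_mean: float = 5.0
    coupling_strength: dict | float = field(default_factory=lambda: DEFAULT_COUPLING)
    noise_sd: float = 0.5
    seed: int = 0
    # generator-shape parameters
    n_modules: int = 3
    phase_lag: float = 0.4  # Sakaguchi frustration angle (rad)
    coupling_gain: float = 1.0  # x (2*pi*bandwidth) at coupling_strength = 1
    burn_in: float = 5.0  # seconds discarded before recording
    template_style: str = "modular"  # or "global" (single all-to-all module)
    observation_shift: float = 1.0  # scale of fixed per-region phase offsets

    def __post_init__(self):
        highest = max(b.high for b in self.bands)
        if self.fs <= 2 * highest:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge {highest}"
            )
        if self.dwell_mean < 1.0:
            raise ValueError("dwell_mean must be >= the 1 s analysis window")
        for c in self._all_couplings():
            if not (0 <= c <= 1):
                raise ValueError("coupling strengths must lie in [0, 1]")
        if self.n_states < 1 or self.n_regions < 2:
            raise ValueError("need n_states >= 1 and n_regions >= 2")

    def _all_couplings(self):
        if isinstance(self.coupling_strength, (int, float)):
            return [float(self.coupling_strength)]
        vals = []
        for per_band in self.coupling_strength.values():
            vals.extend(float(v) for v in per_band.values())
        return vals

    def coupling_for(self, group: str, band: str) -> float:
        if isinstance(self.coupling_strength, (int, float)):
            return float(self.coupling_strength)
        return float(self.coupling_strength.get(group, {}).get(band, _BASE_COUPLING))


def subject_seeds(seed: int, n: int) -> list[int]:
    """Independent per-subject seeds derived from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _state_templates(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Binary coupling masks, one per state (random modular partitions)."""
    n = cfg.n_regions
    templates = np.zeros((cfg.n_states, n, n))
    for s in range(cfg.n_states):
        if cfg.template_style == "global":
            a = np.ones((n, n))
        else:
            assignment = rng.integers(0, cfg.n_modules, size=n)
            a = (assignment[:, None] == assignment[None, :]).astype(float)
        np.fill_diagonal(a, 0.0)
        templates[s] = a
    return templates


def _state_sequence(
    cfg: SimulationConfig, rng: np.random.Generator, n_samples: int
) -> np.ndarray:
    """Semi-Markov state index per sample (exponential dwell times)."""
    seq = np.empty(n_samples, dtype=int)
    t = 0
    state = int(rng.integers(cfg.n_states))
    while t < n_samples:
        dwell = max(1, int(rng.exponential(cfg.dwell_mean) * cfg.fs))
        seq[t : t + dwell] = state
        t += dwell
        if cfg.n_states > 1:
            others = [s for s in range(cfg.n_states) if s != state]
            state = others[int(rng.integers(len(others)))]
    return seq


@njit(cache=True)
def _integrate(omega, templates, degrees, states, gain, alpha, dt, phi0, obs_shift, keep):
    """Euler integration of Kuramoto-Sakaguchi phases; returns sin(phase)
    for the last ``keep`` samples (burn-in discarded)."""
    n = omega.shape[0]
    total = states.shape[0]
    phi = phi0.copy()
    out = np.empty((n, keep))
    dphi = np.empty(n)
    skip = total - keep
    for t in range(total):
        s = states[t]
        if gain > 0.0:
            sin_p = np.sin(phi)
            cos_p = np.cos(phi)
            a = templates[s]
            for i in range(n):
                acc_s = 0.0
                acc_c = 0.0
                for j in range(n):
                    acc_s += a[i, j] * sin_p[j]
                    acc_c += a[i, j] * cos_p[j]
                # sum_j A_ij sin(phi_j - phi_i - alpha)
                coup = (
                    np.cos(phi[i] + alpha) * acc_s - np.sin(phi[i] + alpha) * acc_c
                ) / degrees[s, i]
                dphi[i] = omega[i] + gain * coup
        else:
            for i in range(n):
                dphi[i] = omega[i]
        for i in range(n):
            phi[i] = phi[i] + dt * dphi[i]
        if t >= skip:
            for i in range(n):
                out[i, t - skip] = np.sin(phi[i] + obs_shift[i])
    return out


def simulate_subject_signals(
    cfg: SimulationConfig,
    group: str = "HC",
    return_states: bool = False,
):
    """Simulate one subject's broadband regional signals.

    Per band, phases follow Euler-integrated Kuramoto-Sakaguchi dynamics

        dphi_i/dt = omega_i + (c * gain / deg_i) *
                    sum_j A_ij(t) sin(phi_j - phi_i - alpha)

    where ``A(t)`` switches among the state templates, ``c`` is the group- and
    band-specific coupling strength, and ``gain`` scales with the band width
    so that ``c = 1`` comfortably exceeds the within-module locking threshold.
    The observed signal sums ``sin(phase)`` over bands plus Gaussian noise.
    """
    rng = np.random.default_rng(cfg.seed)
    templates = _state_templates(cfg, rng)
    total = int((cfg.duration + cfg.burn_in) * cfg.fs)
    keep = int(cfg.duration * cfg.fs)
    states = _state_sequence(cfg, rng, total)
    dt = 1.0 / cfg.fs
    n = cfg.n_regions
    data = np.zeros((n, keep))
    degrees = np.maximum(templates.sum(axis=2), 1.0)  # (n_states, n)
    for band in cfg.bands:
        low = max(band.low, 0.2)
        omega = 2 * np.pi * rng.uniform(low, band.high, size=n)
        c = cfg.coupling_for(group, band.name)
        gain = c * cfg.coupling_gain * 2 * np.pi * (band.high - low)
        phi = rng.uniform(-np.pi, np.pi, size=n)
        # fixed per-region observation phase shifts (projection geometry):
        # invisible to CCor (constant offsets cancel in the sine deviations)
        # but they give synchronized regions stable nonzero lags, which the
        # phase-lag index needs to register coupling at all
        obs_shift = rng.uniform(-np.pi, np.pi, size=n) * cfg.observation_shift
        data += _integrate(
            omega, templates, degrees, states, gain, cfg.phase_lag, dt,
            phi, obs_shift, keep,
        )
    if cfg.noise_sd > 0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)
    ts = RegionTimeSeries(
        data=data, fs=cfg.fs, band=None, subject_id=f"{group}-seed{cfg.seed}"
    )
    if return_states:
        return ts, states[total - keep :], templates
    return ts


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

DEFAULT_GROUP_SIZES = {"HC": 29, "CN-CCF": 58, "MCI-LB": 39}

#: clinical-scale group offsets in SD units (patients score higher)
DEFAULT_CLINICAL_OFFSETS = {
    "updrs": {"HC": 0.0, "CN-CCF": 1.2, "MCI-LB": 1.5},
    "mfs": {"HC": 0.0, "CN-CCF": 0.8, "MCI-LB": 1.0},
    "rbdq": {"HC": 0.0, "CN-CCF": 1.0, "MCI-LB": 1.0},
    "npi": {"HC": 0.0, "CN-CCF": 0.5, "MCI-LB": 0.6},
}

#: premorbid-intelligence group offsets (patients slightly lower)
DEFAULT_RESERVE_OFFSETS = {"HC": 0.3, "CN-CCF": 0.1, "MCI-LB": -0.2}


@dataclass
class CohortConfig:
    """Covariate/response structure of the synthetic cohort."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    age_range: tuple[float, float] = (55.0, 80.0)
    effect_map: dict = field(default_factory=dict)  # score -> group -> SD offset
    score_links: dict = field(
        default_factory=lambda: {"executive_function": ("fluidity_delta", 0.3)}
    )
    lc_quadratic: tuple[float, float, float] = (0.0, 0.0, 0.0)
    interaction_gap: float = 0.25  # extra linear LC->fluidity slope, low reserve
    quadratic_gap: float = -0.4  # extra quadratic LC coefficient, low reserve
    noise_sd: float = 0.5
    seed: int = 0
    fluidity_feature: str = "fluidity_delta"

    def __post_init__(self):
        if any(v <= 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if not np.all(np.isfinite(list(self.lc_quadratic))):
            raise ValueError("lc_quadratic coefficients must be finite")


def simulate_cohort(
    cc: CohortConfig, features: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Build a per-subject cohort table, optionally around computed features.

    If ``features`` (indexed or keyed by ``subject_id``) is given, its columns
    are merged and cognitive scores are generated with the configured rank
    correlations to them. If the configured fluidity feature is absent, it is
    *generated* from the LC variable through the configured quadratic +
    low-reserve moderation (standardized variables), which is the mode the
    regression-recovery analyses use.
    """
    rng = np.random.default_rng(cc.seed)
    rows = []
    for grp, size in cc.group_sizes.items():
        for i in range(size):
            rows.append({"subject_id": f"{grp}-{i:03d}", "group": grp})
    df = pd.DataFrame(rows)
    n = len(df)
    df["age"] = rng.uniform(*cc.age_range, size=n).round(1)
    df["sex"] = np.where(rng.random(n) < 0.55, "F", "M")
    reserve_offsets = np.array(
        [DEFAULT_RESERVE_OFFSETS.get(g, 0.0) for g in df["group"]]
    )
    df["premorbid_iq"] = rng.normal(0.0, 1.0, size=n) + reserve_offsets

    if features is not None:
        feats = features.copy()
        if "subject_id" in feats.columns:
            if len(feats) != n:
                raise ValueError("feature table size does not match cohort size")
            feats = feats.drop(columns=["subject_id"])
        elif len(feats) != n:
            raise ValueError("feature table size does not match cohort size")
        for col in feats.columns:
            df[col] = np.asarray(feats[col])

    # LC contrast ratio (standardized latent; downstream scales are arbitrary)
    lc = rng.normal(0.0, 1.0, size=n)
    df["lc_cr"] = 0.15 + 0.03 * lc  # plausible CR scale for reporting
    df["lc_z"] = lc

    if cc.fluidity_feature not in df.columns:
        a, b, c0 = cc.lc_quadratic
        low = df["premorbid_iq"].values <= np.median(df["premorbid_iq"].values)
        response = (
            a * lc**2
            + b * lc
            + c0
            + low * (cc.interaction_gap * lc + cc.quadratic_gap * lc**2)
            + rng.normal(0.0, cc.noise_sd, size=n)
        )
        df[cc.fluidity_feature] = response

    # cognitive-domain scores correlated with designated features
    for score, (feature, rho) in cc.score_links.items():
        if feature in df.columns and np.std(df[feature].values) > 0:
            z = (df[feature] - df[feature].mean()) / df[feature].std()
        else:
            z = np.zeros(n)
        vals = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n)
        offsets = cc.effect_map.get(score, {})
        vals = vals + np.array([offsets.get(g, 0.0) for g in df["group"]])
        df[score] = vals
    for score in ("verbal_memory", "visual_memory"):
        if score not in df.columns:
            offsets = cc.effect_map.get(score, {})
            df[score] = rng.normal(size=n) + np.array(
                [offsets.get(g, 0.0) for g in df["group"]]
            )

    # clinical scales with group offsets
    for scale, offsets in DEFAULT_CLINICAL_OFFSETS.items():
        base = rng.normal(0.0, 1.0, size=n)
        df[scale] = base + np.array([offsets.get(g, 0.0) for g in df["group"]])

    # core-feature counts: HC none, CN-CCF >= 1, MCI-LB 1-3
    counts = np.zeros(n, dtype=float)
    for grp, lo, hi in (("CN-CCF", 1, 2), ("MCI-LB", 1, 3)):
        idx = df.index[df["group"] == grp]
        counts[idx] = rng.integers(lo, hi + 1, size=len(idx))
    df["n_core_features"] = counts
    return df


# ---------------------------------------------------------------------------
# neuromelanin-like volumes
# ---------------------------------------------------------------------------


@dataclass
class VolumeConfig:
    """Geometry and planted contrasts of a synthetic neuromelanin volume."""

    shape: tuple[int, int, int] = (40, 40, 24)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pt_intensity: float = 100.0
    lc_peak_contrast: float | dict = 0.2  # scalar or {"rostral": ..., ...}
    lc_centers: dict = field(
        default_factory=lambda: {"left": (13, 20), "right": (27, 20)}
    )
    middle_slice: int = 12
    slice_spacing: int = 1
    noise_sd: float = 0.0
    ventricle_box: tuple | None = None  # ((i0,i1),(j0,j1),(k0,k1)), end-exclusive
    seed: int = 0
    search_halfwidth: int = 4

    def __post_init__(self):
        if self.pt_intensity <= 0:
            raise ValueError("pt_intensity must be positive")
        for side, (ci, cj) in self.lc_centers.items():
            if not (0 < ci < self.shape[0] - 1 and 0 < cj < self.shape[1] - 1):
                raise ValueError(f"{side} LC center outside the grid interior")

    def contrast_at(self, position: str) -> float:
        if isinstance(self.lc_peak_contrast, dict):
            return float(self.lc_peak_contrast[position])
        return float(self.lc_peak_contrast)


def simulate_nm_volume(vc: VolumeConfig) -> LCVolume:
    """Build a neuromelanin-like volume with exactly planted contrast ratios.

    The whole volume sits at the PT reference level. On each measured slice
    the LC signal is a 5-voxel cross whose *mean* equals
    ``pt_intensity * (1 + contrast)`` with a strictly maximal center voxel, so
    the extractor recovers the planted contrast exactly at zero noise. An
    optional ventricle box (signal void, flagged in the ventricle mask) can be
    placed adjacent to a cross to exercise the shift rule.
    """
    rng = np.random.default_rng(vc.seed)
    nx_, ny, nz = vc.shape
    vol = np.full(vc.shape, vc.pt_intensity, dtype=float)

    positions = {
        "rostral": vc.middle_slice + vc.slice_spacing,
        "middle": vc.middle_slice,
        "caudal": vc.middle_slice - vc.slice_spacing,
    }
    if not all(0 <= z < nz for z in positions.values()):
        raise ValueError("measured slices fall outside the volume")

    search = {s: np.zeros(vc.shape, dtype=bool) for s in vc.lc_centers}
    hw = vc.search_halfwidth
    for side, (ci, cj) in vc.lc_centers.items():
        lo_z = min(positions.values()) - 1
        hi_z = max(positions.values()) + 2
        search[side][
            max(ci - hw, 0) : ci + hw + 1,
            max(cj - hw, 0) : cj + hw + 1,
            max(lo_z, 0) : min(hi_z, nz),
        ] = True

    for side, (ci, cj) in vc.lc_centers.items():
        for position, z in positions.items():
            contrast = vc.contrast_at(position)
            # center +delta, neighbors -delta/4: the cross MEAN equals the
            # target exactly while the center voxel stays strictly maximal
            # with a margin well above typical noise levels
            target = vc.pt_intensity * (1.0 + contrast)
            delta = 0.05 * vc.pt_intensity
            cross = [(ci, cj), (ci - 1, cj), (ci + 1, cj), (ci, cj - 1), (ci, cj + 1)]
            if not all(search[side][i, j, z] for i, j in cross):
                raise ValueError(f"{side} {position} cross leaves the search mask")
            vol[ci, cj, z] = target + delta
            for i, j in cross[1:]:
                vol[i, j, z] = target - delta / 4.0

    # PT reference: central box between the two LC search areas, away from them
    pt_mask = np.zeros(vc.shape, dtype=bool)
    mid_i = nx_ // 2
    pt_mask[mid_i - 2 : mid_i + 3, 4:10, positions["caudal"] : positions["rostral"] + 1] = True
    for side in search:
        if (pt_mask & search[side]).any():
            raise ValueError("PT mask overlaps an LC search mask; adjust geometry")

    ventricle_mask = None
    if vc.ventricle_box is not None:
        (i0, i1), (j0, j1), (k0, k1) = vc.ventricle_box
        ventricle_mask = np.zeros(vc.shape, dtype=bool)
        ventricle_mask[i0:i1, j0:j1, k0:k1] = True
        vol[ventricle_mask] = 0.3 * vc.pt_intensity  # CSF signal void

    if vc.noise_sd > 0:
        noise = rng.normal(0.0, vc.noise_sd, size=vc.shape)
        if ventricle_mask is not None:
            noise[ventricle_mask] = 0.0
        vol = vol + noise

    return LCVolume(
        intensities=vol,
        voxel_size=vc.voxel_size,
        lc_search_masks=search,
        pt_mask=pt_mask,
        ventricle_mask=ventricle_mask,
        slice_axis=2,
        rostral_positive=True,
    )
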