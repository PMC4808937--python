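"""Synthetic bilateral shoulder EMG studies.

Generates complete studies from the generative side of the full model:
patient covariates, a 4-vector of correlated muscle-specific random
intercepts ``nu_i ~ N(0, D)``, and stationary AR(1) residuals per
(muscle, side, movement) series, on the natural-log millivolt scale.

Default truth values mirror a real 202-patient breast-cancer shoulder
study: coefficient magnitudes, autocorrelations around 0.8, residual
variances around 0.3 and random-intercept variances around 0.3 (ln mV)^2,
with positive cross-muscle coupling (correlation 0.5).  Covariate
distributions are configurable stand-ins: binary prevalences, Gaussian age,
uniform post-surgery duration, and right-skewed (gamma) SPADI pain and
disability scores on their 0-500 / 0-800 mm scales.

Randomness is hierarchical: one global seed spawns independent per-patient
and per-series streams, so enlarging a study leaves the data of earlier
patients bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .covariance import AR1Params, ModelParams, N_MUSCLES, RandomEffectsCov
from .data import COVARIATES, MOVEMENTS, MUSCLES, ObservationTable, SIDES, _replace_response
from .design import DesignSpec, build_design, default_design_spec
from .errors import ParameterError

# stream tags for the hierarchical seed tree
_COV_STREAM, _PATIENT_STREAM, _SERIES_STREAM = 0, 1, 2

#: Default true coefficients per design term (PM, UT, SA, RH), log-mV scale,
#: with the /100-scaled covariate convention of the default design.
DEFAULT_TRUE_BETA = {
    "intercept": (3.0662, 3.1566, 2.8413, 2.2559),
    "elevation": (0.5012, 0.5761, 0.8314, 0.694),
    "move_up": (0.1357, 0.299, 0.1362, 0.201),
    "affected": (-0.03653, 0.1271, 0.5837, 0.1368),
    "hand_left": (0.2837, 0.1537, 0.1983, 0.1608),
    "dominant": (0.07391, 0.1057, 0.07586, 0.07687),
    "age": (-0.093, 0.4211, -0.549, 0.4292),
    "duration": (-0.011, 0.0021, 0.0112, 0.0119),
    "spadi_pain": (-0.148, -0.155, -0.064, -0.103),
    "spadi_disability": (0.0533, 0.0679, 0.0604, -0.037),
    "wle": (-0.283, -0.2028, -0.2668, -0.2306),
    "chemo": (-0.1598, -0.1078, -0.4812, -0.1446),
    "elevation:affected": (0.000507, 0.0737, 0.0036, 0.1096),
    "dominant:affected": (-0.2347, -0.1247, -0.3505, -0.2764),
    "duration:affected": (0.0015, -0.008, -0.024, -0.011),
    "spadi_pain:affected": (0.1115, 0.1211, -0.023, 0.1212),
    "exercise_6m@affected": (-0.02175, -0.05333, -0.06286, 0.006382),
    "exercise_now@affected": (0.05879, 0.01727, 0.05089, -0.03237),
    "physio_now@affected": (0.08553, 0.4907, 0.1158, 0.5001),
    "physio_ever@affected": (-0.0337, -0.1669, 0.02314, -0.2484),
}

DEFAULT_RHO = (0.79, 0.85, 0.82, 0.80)
DEFAULT_SIGMA2 = (0.31, 0.37, 0.33, 0.29)
DEFAULT_RE_VARIANCE = (0.33, 0.38, 0.29, 0.35)
DEFAULT_RE_CORRELATION = 0.5


def default_truth(spec: DesignSpec | None = None) -> ModelParams:
    """True parameters used by the default simulation.

    Coefficients for terms without a tabulated default are zero.  D combines
    the default random-intercept variances with a common +0.5 cross-muscle
    correlation.
    """
    spec = spec or default_design_spec()
    beta = np.concatenate(
        [
            [DEFAULT_TRUE_BETA.get(t, (0.0,) * N_MUSCLES)[k] for t in spec.terms]
            for k in range(N_MUSCLES)
        ]
    )
    sd = np.sqrt(np.asarray(DEFAULT_RE_VARIANCE))
    corr = np.full((N_MUSCLES, N_MUSCLES), DEFAULT_RE_CORRELATION)
    np.fill_diagonal(corr, 1.0)
    D = corr * np.outer(sd, sd)
    return ModelParams(
        beta=beta,
        ar1=AR1Params(rho=np.asarray(DEFAULT_RHO), sigma2=np.asarray(DEFAULT_SIGMA2)),
        recov=RandomEffectsCov.full(D),
    )


@dataclass(frozen=True)
class CovariateModel:
    """Distributions of the patient-level covariates (configurable stand-ins)."""

    p_hand_left: float = 0.5
    p_dominant_affected: float = 0.5   # dominant hand on the affected side
    age_mean: float = 55.0             # years
    age_sd: float = 10.0
    duration_range: tuple = (180.0, 2190.0)   # days since surgery (~6 months .. 6 years)
    spadi_pain_shape: float = 1.5      # gamma: right-skewed, mm, capped at 500
    spadi_pain_scale: float = 60.0
    spadi_disability_shape: float = 1.5  # capped at 800
    spadi_disability_scale: float = 90.0
    p_wle: float = 0.7
    p_chemo: float = 0.5
    p_exercise_6m: float = 0.4
    p_exercise_now: float = 0.3
    p_physio_now: float = 0.2
    p_physio_ever: float = 0.6

    def __post_init__(self):
        for name, v in asdict(self).items():
            if name.startswith("p_") and not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be a probability, got {v}")
        if self.age_sd < 0 or self.spadi_pain_shape <= 0 or self.spadi_disability_shape <= 0:
            raise ParameterError("dispersion/shape parameters must be positive")
        lo, hi = self.duration_range
        if not 0 <= lo <= hi:
            raise ParameterError("duration_range must be 0 <= lo <= hi")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic study."""

    n_patients: int = 202
    max_elevation: object = 150   # fixed degrees, or (lo, hi) sampled per patient in steps of 10
    covariates: CovariateModel = field(default_factory=CovariateModel)
    design: DesignSpec = field(default_factory=default_design_spec)
    truth: ModelParams | None = None   # None -> default_truth(design)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        for m in self._elevation_bounds():
            if m < 10 or m % 10 != 0:
                raise ParameterError("max_elevation must be positive multiples of 10")
        t = self.resolved_truth()
        n_fixed = N_MUSCLES * self.design.p_per_muscle
        if t.beta.shape != (n_fixed,):
            raise ParameterError(f"truth beta must have {n_fixed} entries, got {t.beta.shape}")

    def _elevation_bounds(self):
        if isinstance(self.max_elevation, (tuple, list)):
            return tuple(self.max_elevation)
        return (self.max_elevation, self.max_elevation)

    def resolved_truth(self) -> ModelParams:
        return self.truth if self.truth is not None else default_truth(self.design)

    # -- config file round-trip ------------------------------------------
    def to_dict(self) -> dict:
        t = self.resolved_truth()
        p = self.design.p_per_muscle
        return {
            "n_patients": self.n_patients,
            "max_elevation": list(self.max_elevation)
            if isinstance(self.max_elevation, (tuple, list))
            else self.max_elevation,
            "seed": self.seed,
            "covariates": asdict(self.covariates),
            "design": self.design.to_dict(),
            "truth": {
                "beta": {
                    term: [float(t.beta[k * p + j]) for k in range(N_MUSCLES)]
                    for j, term in enumerate(self.design.terms)
                },
                "rho": [float(r) for r in t.ar1.rho],
                "sigma2": [float(s) for s in t.ar1.sigma2],
                "recov_variant": t.recov.variant,
                "D": np.asarray(t.recov.D).tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        design = DesignSpec.from_dict(d["design"]) if "design" in d else default_design_spec()
        cov = d.get("covariates", {})
        if isinstance(cov.get("duration_range"), list):
            cov = dict(cov, duration_range=tuple(cov["duration_range"]))
        truth = None
        td = d.get("truth")
        if td and td != "default":
            terms = design.terms
            beta = np.concatenate(
                [[td["beta"][term][k] for term in terms] for k in range(N_MUSCLES)]
            )
            variant = td.get("recov_variant", "full")
            D = np.asarray(td["D"], dtype=float)
            recov = RandomEffectsCov(variant, D)
            truth = ModelParams(
                beta=beta,
                ar1=AR1Params(rho=np.asarray(td["rho"]), sigma2=np.asarray(td["sigma2"])),
                recov=recov,
            )
        max_elev = d.get("max_elevation", 150)
        if isinstance(max_elev, list):
            max_elev = tuple(max_elev)
        return cls(
            n_patients=int(d.get("n_patients", 202)),
            max_elevation=max_elev,
            covariates=CovariateModel(**cov),
            design=design,
            truth=truth,
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _rng(seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _patient_ids(n: int):
    width = max(4, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def generate_covariates(config: SyntheticConfig) -> pd.DataFrame:
    """One row per patient; deterministic given the config seed.

    Each patient has an independent stream, so the first k patients of a
    larger study equal the k patients of a smaller one.
    """
    cm = config.covariates
    lo, hi = cm.duration_range
    rows = []
    for i, pid in enumerate(_patient_ids(config.n_patients)):
        r = _rng(config.seed, _COV_STREAM, i)
        rows.append(
            {
                "patient_id": pid,
                "hand_left": int(r.random() < cm.p_hand_left),
                "dominant_side_measured": int(r.random() < cm.p_dominant_affected),
                "age_years": float(r.normal(cm.age_mean, cm.age_sd)),
                "duration_days": float(r.uniform(lo, hi)),
                "spadi_pain_mm": float(
                    min(r.gamma(cm.spadi_pain_shape, cm.spadi_pain_scale), 500.0)
                ),
                "spadi_disability_mm": float(
                    min(r.gamma(cm.spadi_disability_shape, cm.spadi_disability_scale), 800.0)
                ),
                "wle": int(r.random() < cm.p_wle),
                "chemo": int(r.random() < cm.p_chemo),
                "exercise_6m": int(r.random() < cm.p_exercise_6m),
                "exercise_now": int(r.random() < cm.p_exercise_now),
                "physio_now": int(r.random() < cm.p_physio_now),
                "physio_ever": int(r.random() < cm.p_physio_ever),
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def _psd_factor(D: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix (eigen-based, tolerates singular D)."""
    w, v = np.linalg.eigh(D)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _ar1_noise(r: np.random.Generator, n: int, rho: float, sigma2: float) -> np.ndarray:
    """Stationary AR(1) vector: e_1 ~ N(0, s2); e_j = rho e_{j-1} + N(0, s2 (1-rho^2))."""
    z = r.standard_normal(n)
    e = np.empty(n)
    e[0] = np.sqrt(sigma2) * z[0]
    innov_sd = np.sqrt(sigma2 * (1.0 - rho ** 2))
    for j in range(1, n):
        e[j] = rho * e[j - 1] + innov_sd * z[j]
    return e


def simulate_study(config: SyntheticConfig) -> ObservationTable:
    """Simulate a complete study from the generative model.

    For each patient draw ``nu_i ~ N(0, D)``; for every
    (muscle, side, movement) series draw a stationary AR(1) Gaussian
    residual with marginal variance sigma2_k and lag-one correlation rho_k;
    the response is ``x'beta + nu_ik + eps`` on the log-mV scale.
    """
    truth = config.resolved_truth()
    if np.any(np.abs(truth.ar1.rho) >= 1) or np.any(truth.ar1.sigma2 < 0):
        raise ParameterError("invalid AR(1) truth parameters")
    cov = generate_covariates(config)
    lo, hi = config._elevation_bounds()
    ids = list(cov.index)

    # per-patient series grid (max elevation possibly sampled)
    n_elev = np.empty(len(ids), dtype=int)
    nus = np.empty((len(ids), N_MUSCLES))
    Lfac = _psd_factor(truth.recov.D)
    for i in range(len(ids)):
        r_pat = _rng(config.seed, _PATIENT_STREAM, i)
        max_elev = 10 * int(r_pat.integers(lo // 10, hi // 10 + 1)) if hi > lo else lo
        n_elev[i] = max_elev // 10
        nus[i] = Lfac @ r_pat.standard_normal(N_MUSCLES)

    n_series = 2 * 2  # sides x movements per muscle
    block_len = N_MUSCLES * n_series * n_elev
    parts = {
        "patient_id": np.repeat(np.asarray(ids, dtype=object), block_len),
        "muscle": np.concatenate([np.repeat(MUSCLES, n_series * n) for n in n_elev]),
        "side": np.concatenate([np.tile(np.repeat(SIDES, 2 * n), N_MUSCLES) for n in n_elev]),
        "movement": np.concatenate(
            [np.tile(np.repeat(MOVEMENTS, n), N_MUSCLES * 2) for n in n_elev]
        ),
        "elevation_deg": np.concatenate(
            [np.tile(np.arange(10, 10 * n + 1, 10), N_MUSCLES * n_series) for n in n_elev]
        ),
    }
    frame = pd.DataFrame(parts)
    frame["log_emg"] = 0.0
    for c in COVARIATES:
        frame[c] = cov[c].to_numpy().repeat(block_len)
    table = ObservationTable(frame)

    design = build_design(table, config.design)
    y = design.X @ truth.beta

    pid_to_idx = {pid: i for i, pid in enumerate(ids)}
    lay = table.layout.frame
    series_counter = {}
    for pid, k, start, stop, n_i in zip(
        lay["patient_id"], lay["muscle_idx"], lay["start"], lay["stop"], lay["n_i"]
    ):
        i = pid_to_idx[pid]
        s = series_counter.get(i, 0)
        series_counter[i] = s + 1
        r_ser = _rng(config.seed, _SERIES_STREAM, i, s)
        eps = _ar1_noise(r_ser, int(n_i), truth.ar1.rho[k], truth.ar1.sigma2[k])
        y[start:stop] += nus[i, k] + eps

    return _replace_response(table, y)
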