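"""Synthetic OSA cohort generation via a Gaussian copula.

The generator reproduces the statistical structure of a sleep-unit referral
cohort: each clinical or phenotypic variable follows a bounded marginal
distribution (truncated normal, or a shifted lognormal for the right-skewed
apnea-hypopnea index), and the joint dependence is a Gaussian copula whose
parameters are chosen so the *rank* (Spearman) correlations match a target
matrix.  Marginal parameters are calibrated numerically so that the
*truncated* distribution has exactly the requested mean and standard
deviation — printed cohort tables describe observed, in-range data, so the
calibration treats them as moments of the truncated law, not of a latent
unbounded one.

Body-mass index is a first-class copula variable (its correlations with the
apnea-hypopnea index and the craniofacial features are direct generator
targets); weight is derived per subject as ``bmi * (height_m)**2`` so the
BMI identity holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

__all__ = [
    "MarginalSpec",
    "CohortSpec",
    "GroupConditionalSpec",
    "SubjectRecord",
    "build_reference_spec",
    "generate_cohort",
    "generate_group_cohort",
    "sample_copula",
    "spearman_to_pearson",
    "nearest_psd_correlation",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
]

CLINICAL_VARS = ("ahi", "height", "age", "cervical_perimeter", "bmi")
CRANIOFACIAL_VARS = ("cervicomental_ratio", "face_width_ratio", "trs_angle")


# --------------------------------------------------------------------------
# marginal specification and calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MarginalSpec:
    """A bounded univariate marginal with target observed moments.

    ``mean``/``sd`` are the moments the *truncated* distribution must attain
    on [low, high]; ``family`` selects truncated-normal or a lognormal
    shifted to start at ``low`` (used for the apnea-hypopnea index, whose
    sd exceeds its mean and which is bounded below at zero).
    """

    name: str
    mean: float
    sd: float
    low: float
    high: float
    family: str = "truncated-normal"  # or "log-shifted"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")
        if not (self.low <= self.mean <= self.high):
            raise ValueError(f"{self.name}: mean outside [low, high]")
        if self.family not in ("truncated-normal", "log-shifted"):
            raise ValueError(f"{self.name}: unknown family {self.family!r}")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function of the calibrated, truncated marginal."""
        if self.sd == 0.0:
            return np.full_like(np.asarray(u, dtype=float), self.mean)
        if self.family == "truncated-normal":
            loc, scale = _calibrate_truncnorm(self.mean, self.sd, self.low, self.high)
            a = (self.low - loc) / scale
            b = (self.high - loc) / scale
            return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)
        mu, sigma = _calibrate_lognorm(
            self.mean - self.low, self.sd, self.high - self.low
        )
        dist = stats.lognorm(s=sigma, scale=math.exp(mu))
        zc = dist.cdf(self.high - self.low)
        return self.low + dist.ppf(np.asarray(u) * zc)


@lru_cache(maxsize=512)
def _calibrate_truncnorm(mean: float, sd: float, low: float, high: float):
    """Solve (loc, scale) so truncnorm on [low, high] has the given moments."""

    def resid(p):
        loc, log_scale = p
        scale = math.exp(log_scale)
        a, b = (low - loc) / scale, (high - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [float(m) - mean, math.sqrt(max(float(v), 1e-300)) - sd]

    sol = optimize.root(resid, x0=[mean, math.log(sd)], method="hybr")
    loc, scale = float(sol.x[0]), float(math.exp(sol.x[1]))
    if not sol.success:  # fall back to least squares from the same start
        ls = optimize.least_squares(resid, x0=[mean, math.log(sd)])
        loc, scale = float(ls.x[0]), float(math.exp(ls.x[1]))
    return loc, scale


@lru_cache(maxsize=512)
def _calibrate_lognorm(mean: float, sd: float, cap: float):
    """Solve lognormal (mu, sigma) so the [0, cap]-truncated law has the moments.

    Truncated raw moments of a lognormal are closed-form:
    E[X^k | X<=c] = exp(k*mu + k^2 sigma^2/2) * Phi((ln c - mu - k sigma^2)/sigma) / Phi((ln c - mu)/sigma).
    """

    def moments(mu, sigma):
        lc = math.log(cap)
        z = ndtr((lc - mu) / sigma)
        with np.errstate(over="ignore"):
            m1 = np.exp(mu + 0.5 * sigma**2) * ndtr((lc - mu - sigma**2) / sigma) / z
            m2 = np.exp(2 * mu + 2 * sigma**2) * ndtr((lc - mu - 2 * sigma**2) / sigma) / z
        return m1, math.sqrt(max(m2 - m1 * m1, 1e-300))

    def resid(p):
        # clamp the solver's excursions so the closed-form moments stay finite
        mu = float(np.clip(p[0], -50.0, 50.0))
        sigma = float(math.exp(np.clip(p[1], -6.0, 3.0)))
        m1, s1 = moments(mu, sigma)
        if not (np.isfinite(m1) and np.isfinite(s1)):
            return [1e6, 1e6]
        return [m1 - mean, s1 - sd]

    # untruncated moment-matching start
    sigma0 = math.sqrt(math.log1p((sd / mean) ** 2))
    mu0 = math.log(mean) - 0.5 * sigma0**2
    sol = optimize.root(resid, x0=[mu0, math.log(sigma0)], method="hybr")
    if not sol.success:
        sol = optimize.least_squares(resid, x0=[mu0, math.log(sigma0)])
    mu = float(np.clip(sol.x[0], -50.0, 50.0))
    sigma = float(math.exp(np.clip(sol.x[1], -6.0, 3.0)))
    return mu, sigma


# --------------------------------------------------------------------------
# cohort specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Marginals plus a target Spearman correlation matrix for one sex."""

    sex: str
    marginals: tuple[MarginalSpec, ...]
    rank_corr: np.ndarray
    n: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        r = np.asarray(self.rank_corr, dtype=float)
        k = len(self.marginals)
        if r.shape != (k, k):
            raise ValueError("rank_corr shape must match number of marginals")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("rank_corr must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValueError("rank_corr must have unit diagonal")
        if np.any(np.abs(r) > 1.0 + 1e-12):
            raise ValueError("rank_corr entries must lie in [-1, 1]")
        object.__setattr__(self, "rank_corr", r)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.marginals)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def rho(self, a: str, b: str) -> float:
        """Target Spearman correlation between two named variables."""
        return float(self.rank_corr[self.index(a), self.index(b)])


@dataclass(frozen=True)
class GroupConditionalSpec:
    """Per-group overrides of marginal mean/sd, with an AHI support window."""

    group: str  # control | osa | mild | severe
    overrides: dict = field(default_factory=dict)  # name -> (mean, sd)
    ahi_support: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        bounds = {
            "control": (0.0, 10.0),
            "osa": (10.0, math.inf),
            "mild": (10.0, 30.0),
            "severe": (30.0, math.inf),
        }
        if self.group not in bounds:
            raise ValueError(f"unknown group {self.group!r}")
        if self.ahi_support is None:
            object.__setattr__(self, "ahi_support", bounds[self.group])
        lo, hi = bounds[self.group]
        if "ahi" in self.overrides:
            m = self.overrides["ahi"][0]
            if not (lo <= m <= hi):
                raise ValueError(
                    f"{self.group}: AHI mean {m} outside group support [{lo}, {hi}]"
                )


@dataclass
class SubjectRecord:
    """One simulated subject: clinical variables plus named features."""

    subject_id: str
    sex: str
    ahi: float
    weight: float
    height: float
    age: float
    cervical_perimeter: float
    features: dict = field(default_factory=dict)

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2

    def __post_init__(self) -> None:
        if self.ahi < 0:
            raise ValueError("ahi must be >= 0")


# --------------------------------------------------------------------------
# reference table parameters
# --------------------------------------------------------------------------

# clinical descriptive statistics: mean, sd, (low, high)
_CLINICAL_TABLE = {
    "female": {
        "ahi": (14.6, 17.0, 0.0, 108.4, "log-shifted"),
        "height": (161.1, 6.4, 148.0, 178.0, "truncated-normal"),
        "age": (50.9, 11.6, 25.0, 88.0, "truncated-normal"),
        "cervical_perimeter": (36.7, 2.9, 30.0, 45.0, "truncated-normal"),
        "bmi": (30.1, 6.9, 18.6, 63.7, "truncated-normal"),
    },
    "male": {
        "ahi": (22.3, 19.0, 0.0, 87.0, "log-shifted"),
        "height": (175.8, 6.9, 160.0, 194.0, "truncated-normal"),
        "age": (48.2, 11.9, 21.0, 78.0, "truncated-normal"),
        "cervical_perimeter": (42.5, 3.2, 34.0, 53.0, "truncated-normal"),
        "bmi": (29.9, 4.9, 20.1, 52.3, "truncated-normal"),
    },
}

# craniofacial measurement descriptive statistics
_CRANIOFACIAL_TABLE = {
    "female": {
        "cervicomental_ratio": (0.6, 0.1, 0.4, 0.9),
        "face_width_ratio": (1.4, 0.1, 0.3, 1.6),
        "trs_angle": (113.2, 5.7, 97.7, 123.7),
    },
    "male": {
        "cervicomental_ratio": (0.6, 0.09, 0.3, 0.8),
        "face_width_ratio": (1.5, 0.06, 1.2, 1.7),
        "trs_angle": (115.5, 6.22, 98.4, 130.4),
    },
}

# female sustained-vowel formant/bandwidth descriptive statistics
VOWEL_TABLE_FEMALE = {
    "a": {
        "F1": (859.6, 89.4, 624.4, 1070.4), "F2": (1454.0, 105.0, 1174.7, 1687.7),
        "F3": (2837.2, 221.3, 2186.9, 3368.6), "BW1": (226.7, 78.7, 57.5, 486.5),
        "BW2": (196.6, 82.0, 76.0, 532.6), "BW3": (223.2, 97.4, 83.3, 576.1),
    },
    "e": {
        "F1": (489.7, 45.8, 377.8, 624.3), "F2": (2268.4, 141.7, 1880.9, 2599.9),
        "F3": (2917.7, 159.3, 2597.2, 3328.2), "BW1": (98.8, 46.3, 22.0, 266.7),
        "BW2": (143.1, 55.4, 34.0, 310.4), "BW3": (229.8, 81.1, 73.7, 473.9),
    },
    "i": {
        "F1": (368.1, 42.2, 243.1, 481.5), "F2": (2620.0, 150.9, 2178.0, 2993.2),
        "F3": (3170.7, 207.3, 2665.6, 3645.9), "BW1": (68.6, 36.7, 12.2, 219.6),
        "BW2": (131.1, 55.3, 40.3, 348.5), "BW3": (236.7, 74.7, 86.8, 441.4),
    },
    "o": {
        "F1": (537.6, 50.8, 410.4, 664.4), "F2": (982.2, 90.5, 758.2, 1243.4),
        "F3": (2881.8, 215.8, 2401.8, 3444.9), "BW1": (127.7, 61.6, 24.9, 360.5),
        "BW2": (141.2, 67.5, 15.4, 395.1), "BW3": (155.1, 67.1, 32.9, 339.7),
    },
    "u": {
        "F1": (379.3, 49.6, 254.6, 509.6), "F2": (823.1, 101.6, 596.0, 1157.9),
        "F3": (2824.7, 243.1, 2285.7, 3790.5), "BW1": (70.7, 35.6, 8.2, 199.2),
        "BW2": (152.6, 122.0, 9.0, 569.9), "BW3": (213.8, 121.5, 53.4, 636.2),
    },
}

# significant Spearman correlations with AHI (clinical variables)
_CLINICAL_CORR = {
    "female": {("height", "ahi"): -0.24, ("age", "ahi"): 0.52,
               ("cervical_perimeter", "ahi"): 0.27, ("bmi", "ahi"): 0.22},
    "male": {("age", "ahi"): 0.15, ("cervical_perimeter", "ahi"): 0.42,
             ("bmi", "ahi"): 0.37},
}

# significant Spearman correlations craniofacial-feature x clinical variable
# (weight cells are omitted: weight is derived from bmi and height here)
_CRANIOFACIAL_CORR = {
    "female": {
        ("cervicomental_ratio", "ahi"): -0.23,
        ("cervicomental_ratio", "cervical_perimeter"): -0.58,
        ("cervicomental_ratio", "bmi"): -0.66,
        ("face_width_ratio", "ahi"): 0.18,
        ("face_width_ratio", "height"): -0.21,
        ("face_width_ratio", "bmi"): 0.22,
        ("trs_angle", "ahi"): -0.19,
        ("trs_angle", "age"): -0.24,
    },
    "male": {
        ("cervicomental_ratio", "ahi"): -0.37,
        ("cervicomental_ratio", "age"): -0.17,
        ("cervicomental_ratio", "cervical_perimeter"): -0.57,
        ("cervicomental_ratio", "bmi"): -0.59,
        ("face_width_ratio", "ahi"): 0.23,
        ("face_width_ratio", "cervical_perimeter"): 0.17,
        ("face_width_ratio", "bmi"): 0.25,
        ("trs_angle", "ahi"): -0.12,
    },
}

# significant formant/bandwidth x clinical correlations, female population
_SPEECH_CORR_FEMALE = {
    ("F1_a", "ahi"): -0.26, ("F1_a", "age"): -0.25, ("F1_a", "cervical_perimeter"): -0.24,
    ("F2_a", "age"): -0.20,
    ("F3_a", "age"): -0.25, ("F3_a", "cervical_perimeter"): -0.21,
    ("BW1_a", "bmi"): -0.19,
    ("BW2_a", "age"): -0.17,
    ("F2_e", "ahi"): -0.24, ("F2_e", "age"): -0.19,
    ("F3_e", "age"): -0.22,
    ("BW2_e", "age"): -0.21,
    ("F2_i", "ahi"): -0.26,
    ("F2_o", "age"): -0.20, ("F2_o", "cervical_perimeter"): -0.20,
    ("F3_o", "age"): -0.21, ("F3_o", "cervical_perimeter"): -0.17,
    ("BW3_o", "height"): -0.27,
    ("F2_u", "age"): -0.18,
}

# female group-conditional (control AHI<10 vs OSA AHI>=10) mean/sd overrides
GROUP_TABLE_FEMALE = {
    "control": {
        "ahi": (4.0, 3.1), "age": (45.4, 10.4), "bmi": (29.0, 7.1),
        "cervical_perimeter": (36.0, 2.8),
        "F2_e": (2303.5, 129.2), "F2_i": (2664.0, 150.7), "F3_i": (3210.4, 203.5),
        "BW2_e": (152.3, 52.5),
        "cervicomental_ratio": (0.6, 0.1), "face_width_ratio": (1.4, 0.05),
        "trs_angle": (114.2, 5.0),
    },
    "osa": {
        "ahi": (25.4, 18.5), "age": (56.5, 10.0), "bmi": (31.2, 6.6),
        "cervical_perimeter": (37.5, 2.9),
        "F2_e": (2232.7, 145.8), "F2_i": (2575.3, 138.5), "F3_i": (3130.0, 204.9),
        "BW2_e": (133.9, 57.0),
        "cervicomental_ratio": (0.6, 0.1), "face_width_ratio": (1.4, 0.06),
        "trs_angle": (112.0, 6.2),
    },
}


def build_reference_spec(
    sex: str,
    features: str = "none",
    n: int = 0,
    seed: int = 0,
) -> CohortSpec:
    """Assemble the reference cohort spec for one sex from the study tables.

    Parameters
    ----------
    sex
        "female" or "male".
    features
        Which feature block to attach to the clinical core:
        "none", "craniofacial", "speech" (female only), or "all".
    """
    if sex not in _CLINICAL_TABLE:
        raise ValueError("sex must be 'female' or 'male'")
    if features not in ("none", "craniofacial", "speech", "all"):
        raise ValueError(f"unknown feature block {features!r}")
    if features in ("speech", "all") and sex != "female":
        raise ValueError("speech feature marginals are available for females only")

    marginals = [
        MarginalSpec(name, m, s, lo, hi, fam)
        for name, (m, s, lo, hi, fam) in _CLINICAL_TABLE[sex].items()
    ]
    corr_entries = dict(_CLINICAL_CORR[sex])

    if features in ("craniofacial", "all"):
        for name, (m, s, lo, hi) in _CRANIOFACIAL_TABLE[sex].items():
            marginals.append(MarginalSpec(name, m, s, lo, hi))
        corr_entries.update(_CRANIOFACIAL_CORR[sex])
    if features in ("speech", "all"):
        for vowel, params in VOWEL_TABLE_FEMALE.items():
            for sym, (m, s, lo, hi) in params.items():
                marginals.append(MarginalSpec(f"{sym}_{vowel}", m, s, lo, hi))
        corr_entries.update(_SPEECH_CORR_FEMALE)

    names = [m.name for m in marginals]
    k = len(names)
    r = np.eye(k)
    for (a, b), rho in corr_entries.items():
        i, j = names.index(a), names.index(b)
        r[i, j] = r[j, i] = rho
    return CohortSpec(sex=sex, marginals=tuple(marginals), rank_corr=r, n=n, seed=seed)


# --------------------------------------------------------------------------
# copula machinery
# --------------------------------------------------------------------------

def spearman_to_pearson(rho: np.ndarray) -> np.ndarray:
    """Exact Gaussian-copula conversion r = 2*sin(pi*rho_S/6)."""
    return 2.0 * np.sin(np.pi * np.asarray(rho, dtype=float) / 6.0)


def nearest_psd_correlation(
    corr: np.ndarray, eig_floor: float = 1e-6, max_defect: float = 0.5
) -> np.ndarray:
    """Repair an indefinite correlation matrix by eigenvalue clipping.

    Eigenvalues below ``eig_floor`` are raised to it, the matrix is
    reassembled and renormalized to unit diagonal.  A matrix whose most
    negative eigenvalue exceeds ``max_defect`` in magnitude is rejected as
    an invalid specification rather than silently distorted.
    """
    c = np.asarray(corr, dtype=float)
    w, v = np.linalg.eigh(c)
    if w.min() < -max_defect:
        raise ValueError(
            f"correlation matrix too indefinite to repair (min eig {w.min():.3f})"
        )
    if w.min() >= eig_floor:
        return c
    w = np.clip(w, eig_floor, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


def sample_copula(
    marginals: tuple[MarginalSpec, ...],
    rank_corr: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw n joint samples with the given marginals and Spearman structure."""
    pearson = nearest_psd_correlation(spearman_to_pearson(rank_corr))
    # jitter guard: clipping can leave the matrix numerically semi-definite
    try:
        chol = np.linalg.cholesky(pearson)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(pearson + 1e-10 * np.eye(len(marginals)))
    z = rng.standard_normal((n, len(marginals))) @ chol.T
    u = ndtr(z)
    # keep quantiles strictly inside (0,1) for the bounded ppfs
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    data = {m.name: m.ppf(u[:, i]) for i, m in enumerate(marginals)}
    return pd.DataFrame(data)


def _records_from_frame(
    frame: pd.DataFrame, sex: str, id_prefix: str = "S"
) -> list[SubjectRecord]:
    missing = [v for v in CLINICAL_VARS if v not in frame.columns]
    if missing:
        raise ValueError(f"cohort frame missing clinical variables: {missing}")
    records = []
    clinical = set(CLINICAL_VARS)
    for i, row in enumerate(frame.itertuples(index=False)):
        d = row._asdict()
        weight = d["bmi"] * (d["height"] / 100.0) ** 2
        records.append(
            SubjectRecord(
                subject_id=f"{id_prefix}{i:05d}",
                sex=sex,
                ahi=float(d["ahi"]),
                weight=float(weight),
                height=float(d["height"]),
                age=float(d["age"]),
                cervical_perimeter=float(d["cervical_perimeter"]),
                features={k: float(v) for k, v in d.items() if k not in clinical},
            )
        )
    return records


def generate_cohort(spec: CohortSpec, n: int | None = None) -> list[SubjectRecord]:
    """Generate a synthetic cohort; deterministic for a fixed spec seed."""
    n = spec.n if n is None else n
    if n < 2:
        raise ValueError("cohort size must be >= 2")
    rng = np.random.default_rng(spec.seed)
    frame = sample_copula(spec.marginals, spec.rank_corr, n, rng)
    return _records_from_frame(frame, spec.sex)


def generate_group_cohort(
    spec: CohortSpec,
    groups: list[GroupConditionalSpec],
    sizes: list[int],
) -> list[SubjectRecord]:
    """Generate severity-labelled subcohorts with conditional marginals.

    Each group reuses the base spec's rank correlation but replaces marginal
    mean/sd with the group's overrides and restricts the AHI support to the
    group's severity window, so every generated subject's AHI is consistent
    with its label.
    """
    if len(groups) != len(sizes):
        raise ValueError("groups and sizes must have equal length")
    records: list[SubjectRecord] = []
    for gi, (group, size) in enumerate(zip(groups, sizes)):
        marginals = []
        for m in spec.marginals:
            mean, sd = group.overrides.get(m.name, (m.mean, m.sd))
            low, high = m.low, m.high
            if m.name == "ahi":
                lo_g, hi_g = group.ahi_support
                low = max(low, lo_g)
                high = min(high, hi_g) if math.isfinite(hi_g) else high
                if not (low <= mean <= high):
                    raise ValueError(
                        f"group {group.group}: AHI mean {mean} outside support"
                    )
            else:
                # keep the base range but widen if an override mean sits
                # too close to a bound for the requested sd
                low = min(low, mean - 4.0 * sd)
                high = max(high, mean + 4.0 * sd)
            marginals.append(replace(m, mean=mean, sd=sd, low=low, high=high))
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, gi]))
        frame = sample_copula(tuple(marginals), spec.rank_corr, size, rng)
        recs = _records_from_frame(frame, spec.sex, id_prefix=f"{group.group[:1].upper()}")
        for r in recs:
            r.features["group"] = group.group
        records.extend(recs)
    return records


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate records: one row per subject, clinical columns then features."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id, "sex": r.sex, "ahi": r.ahi,
            "weight": r.weight, "height": r.height, "bmi": r.bmi,
            "age": r.age, "cervical_perimeter": r.cervical_perimeter,
        }
        row.update(r.features)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(records: list[SubjectRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
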