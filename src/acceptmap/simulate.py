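"""Synthetic reference corpora and medicine evaluation sets.

The multi-country corpus behind the published reference framework cannot
be shared, so this module generates evaluation sets with *planted*
acceptability structure: a two-component mixture of latent profiles
("Positively accepted" / "Negatively accepted"), each profile being a
product of per-variable categorical distributions.  Conditional on the
latent profile the nine variables are drawn independently — the simplest
structure in which profile membership drives all associations between the
21 observed measures (a documented limitation: real evaluations surely
carry residual within-profile dependence).

Default study conditions: a reference corpus of 2,611 evaluations with a
60/40 positive/negative mixture; medicines of 58 patients observed at 3
timepoints with per-patient profile persistence; patient metadata drawn
to mirror the cefaclor study population (72% boys, 90% first exposure,
age-group weights 11/24/16/7, treatment duration 3-14 days, dosing
frequency mostly 3/day).  Missingness, when injected, is MCAR per cell.
Latent labels are retained on the returned sets for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import DEFAULT_CODEBOOK, Codebook
from .schema import EvaluationSet

__all__ = [
    "CorpusConfig",
    "ProfileSpec",
    "default_profiles",
    "generate_medicine",
    "generate_reference",
    "inject_missing",
    "population_barycenter",
]

logger = logging.getLogger(__name__)

POSITIVE_NAME = "Positively accepted"
NEGATIVE_NAME = "Negatively accepted"

REFERENCE_N = 2611  # size of the pooled corpus the published framework used
DEFAULT_MIXTURE = 0.6
STUDY_N_PATIENTS = 58
AGE_GROUP_WEIGHTS = {"0-2": 11 / 58, "3-5": 24 / 58, "6-11": 16 / 58, "12-17": 7 / 58}
AGE_GROUP_RANGES = {"0-2": (0.0, 3.0), "3-5": (3.0, 6.0), "6-11": (6.0, 12.0), "12-17": (12.0, 18.0)}


@dataclass(frozen=True)
class ProfileSpec:
    """A latent acceptability profile: one categorical law per variable."""

    name: str
    distributions: dict[str, tuple[float, ...]]
    codebook: Codebook = field(default=DEFAULT_CODEBOOK)

    def __post_init__(self):
        for var in self.codebook.variable_names:
            if var not in self.distributions:
                raise ValueError(f"profile {self.name!r} lacks variable {var!r}")
            p = np.asarray(self.distributions[var], dtype=float)
            if len(p) != len(self.codebook.categories(var)):
                raise ValueError(f"wrong number of probabilities for {var!r}")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"probabilities for {var!r} sum to {p.sum()}, not 1")
            if (p < 0).any():
                raise ValueError(f"negative probability for {var!r}")

    def fuzzy_row(self) -> np.ndarray:
        """Concatenated probability vector over the 21 codebook columns."""
        return np.concatenate(
            [np.asarray(self.distributions[v], dtype=float) for v in self.codebook.variable_names]
        )


@dataclass(frozen=True)
class CorpusConfig:
    n_evaluations: int = REFERENCE_N
    mixture_weight: float = DEFAULT_MIXTURE  # P(positive profile)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError("mixture_weight must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_evaluations < 2:
            raise ValueError("n_evaluations must be at least 2")


def default_profiles(codebook: Codebook | None = None) -> tuple[ProfileSpec, ProfileSpec]:
    """The default positive/negative profiles.

    The positive profile puts at least 0.85 mass on every positively
    connoted category; the negative profile puts the majority of its mass
    on negatively connoted categories of result_intake, reaction and
    restraint, mirroring the qualitative cluster descriptions.
    """
    codebook = codebook or DEFAULT_CODEBOOK
    positive = ProfileSpec(
        name=POSITIVE_NAME,
        distributions={
            "result_intake": (0.90, 0.07, 0.03),
            "reaction": (0.85, 0.12, 0.03),
            "prep_admin_time": (0.85, 0.10, 0.05),
            "divided_dose": (0.92, 0.08),
            "food_drink": (0.92, 0.08),
            "alteration": (0.92, 0.08),
            "extra_device": (0.92, 0.08),
            "reward": (0.92, 0.08),
            "restraint": (0.92, 0.08),
        },
        codebook=codebook,
    )
    negative = ProfileSpec(
        name=NEGATIVE_NAME,
        distributions={
            "result_intake": (0.20, 0.40, 0.40),
            "reaction": (0.10, 0.30, 0.60),
            "prep_admin_time": (0.10, 0.35, 0.55),
            "divided_dose": (0.45, 0.55),
            "food_drink": (0.40, 0.60),
            "alteration": (0.55, 0.45),
            "extra_device": (0.40, 0.60),
            "reward": (0.60, 0.40),
            "restraint": (0.35, 0.65),
        },
        codebook=codebook,
    )
    return positive, negative


def _sample_categories(
    rng: np.random.Generator,
    profile_of_row: np.ndarray,  # 0 = positive, 1 = negative
    profiles: tuple[ProfileSpec, ProfileSpec],
    codebook: Codebook,
) -> pd.DataFrame:
    n = len(profile_of_row)
    out = {}
    for var in codebook.variable_names:
        cats = np.asarray(codebook.categories(var), dtype=object)
        u = rng.random(n)
        vals = np.empty(n, dtype=object)
        for which, prof in enumerate(profiles):
            mask = profile_of_row == which
            if not mask.any():
                continue
            cum = np.cumsum(prof.distributions[var])
            vals[mask] = cats[np.searchsorted(cum, u[mask], side="right").clip(0, len(cats) - 1)]
        out[var] = vals
    return pd.DataFrame(out)


def _sample_meta(rng: np.random.Generator, patient_ids: list[str]) -> pd.DataFrame:
    n = len(patient_ids)
    groups = rng.choice(
        list(AGE_GROUP_WEIGHTS), size=n, p=list(AGE_GROUP_WEIGHTS.values())
    )
    ages = np.array([rng.uniform(*AGE_GROUP_RANGES[g]) for g in groups])
    meta = pd.DataFrame(
        {
            "age_years": np.clip(np.round(ages, 1), 0.0, 17.9),
            "sex": np.where(rng.random(n) < 0.72, "M", "F"),
            "first_exposure": rng.random(n) < 0.90,
            "dosing_frequency": rng.choice([3, 1, 5], size=n, p=[0.76, 0.22, 0.02]),
            "treatment_duration": rng.integers(3, 15, size=n),
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )
    return meta


def generate_reference(
    config: CorpusConfig,
    positive: ProfileSpec | None = None,
    negative: ProfileSpec | None = None,
    codebook: Codebook | None = None,
) -> EvaluationSet:
    """Generate an i.i.d. reference corpus from the two-profile mixture.

    Each evaluation draws its latent profile Bernoulli(mixture_weight),
    then each variable independently from that profile's distribution.
    Deterministic given the config seed; the latent labels are kept on
    ``latent_profile`` for recovery tests.
    """
    codebook = codebook or DEFAULT_CODEBOOK
    if positive is None or negative is None:
        positive, negative = default_profiles(codebook)
    if all(
        np.allclose(positive.distributions[v], negative.distributions[v])
        for v in codebook.variable_names
    ):
        logger.warning("degenerate profiles: positive and negative are identical")
    rng = np.random.default_rng(config.seed)
    n = config.n_evaluations
    is_negative = (rng.random(n) >= config.mixture_weight).astype(int)
    cat = _sample_categories(rng, is_negative, (positive, negative), codebook)
    pids = [f"E{i + 1:05d}" for i in range(n)]
    ev = pd.concat(
        [pd.DataFrame({"patient_id": pids, "timepoint": 1}), cat], axis=1
    )
    meta = _sample_meta(rng, pids)
    latent = pd.Series(
        np.where(is_negative == 0, positive.name, negative.name), name="latent_profile"
    )
    out = EvaluationSet(evaluations=ev, meta=meta, codebook=codebook, latent_profile=latent)
    if config.missing_rate > 0:
        out = inject_missing(out, config.missing_rate, seed=config.seed + 1)
    return out


def generate_medicine(
    n_patients: int = STUDY_N_PATIENTS,
    timepoints: tuple[int, ...] = (1, 2, 3),
    profile_mix: float = 1.0,
    seed: int = 0,
    positive: ProfileSpec | None = None,
    negative: ProfileSpec | None = None,
    codebook: Codebook | None = None,
) -> EvaluationSet:
    """Generate one medicine's evaluation set: patients x timepoints.

    Each patient's latent profile is drawn once (Bernoulli(profile_mix)
    for the positive profile) and persists across timepoints.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    codebook = codebook or DEFAULT_CODEBOOK
    if positive is None or negative is None:
        positive, negative = default_profiles(codebook)
    rng = np.random.default_rng(seed)
    pids = [f"P{i + 1:03d}" for i in range(n_patients)]
    patient_negative = (rng.random(n_patients) >= profile_mix).astype(int)
    rows_negative = np.repeat(patient_negative, len(timepoints))
    cat = _sample_categories(rng, rows_negative, (positive, negative), codebook)
    ev = pd.concat(
        [
            pd.DataFrame(
                {
                    "patient_id": np.repeat(pids, len(timepoints)),
                    "timepoint": np.tile(list(timepoints), n_patients),
                }
            ),
            cat,
        ],
        axis=1,
    )
    meta = _sample_meta(rng, pids)
    # end-of-treatment adherence: positive-profile patients adhere well
    bands = np.where(
        rng.random(n_patients) < np.where(patient_negative == 0, 0.96, 0.30),
        "81-100",
        "61-80",
    )
    adherence = pd.DataFrame(
        {"band": bands, "difficulty": rng.random(n_patients) < 0.05},
        index=pd.Index(pids, name="patient_id"),
    )
    latent = pd.Series(
        np.where(rows_negative == 0, positive.name, negative.name), name="latent_profile"
    )
    return EvaluationSet(
        evaluations=ev,
        meta=meta,
        adherence=adherence,
        codebook=codebook,
        latent_profile=latent,
    )


def inject_missing(evalset: EvaluationSet, rate: float, seed: int) -> EvaluationSet:
    """Set each observational cell missing independently with prob ``rate``.

    MCAR by construction; metadata and adherence are untouched.  The mask
    is reproducible given the seed.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = evalset.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    vars_ = evalset.codebook.variable_names
    mask = rng.random((len(evalset), len(vars_))) < rate
    obs = out.evaluations[vars_].to_numpy(dtype=object)
    obs[mask] = np.nan
    out.evaluations[vars_] = obs
    return out


def coverage_experiment(
    framework,
    profile: ProfileSpec,
    n_replicates: int = 1000,
    n_per_replicate: int = 58,
    level: float = 0.90,
    seed: int = 0,
) -> dict:
    """Empirical coverage of the barycenter confidence ellipses.

    Repeatedly draws ``n_per_replicate`` evaluations from ``profile``,
    scores them on the fixed ``framework``, and records, per dimension
    pair, whether the level-``level`` ellipse contains the population
    barycenter (the profile's expected map position).  Returns per-pair
    coverage fractions and their mean; each should be close to ``level``.
    """
    from .scoring import DIMENSION_PAIRS, ellipse_quantile

    codebook = profile.codebook
    if framework.mca_.dropped_columns_:
        raise ValueError("coverage experiment requires a model with all 21 categories")
    target = population_barycenter(profile, framework)
    G = framework.mca_.column_coordinates_.to_numpy()
    lam = framework.mca_.eigenvalues_[: framework.mca_.n_components]
    q = ellipse_quantile(n_per_replicate, level)
    rng = np.random.default_rng(seed)
    n_vars = len(codebook.variable_names)
    cums = [np.cumsum(profile.distributions[v]) for v in codebook.variable_names]
    offsets = np.cumsum([0] + [len(codebook.categories(v)) for v in codebook.variable_names])[:-1]
    hits = np.zeros(len(DIMENSION_PAIRS), dtype=int)
    for _ in range(n_replicates):
        Z = np.zeros((n_per_replicate, codebook.n_categories))
        u = rng.random((n_per_replicate, n_vars))
        for j, (cum, off) in enumerate(zip(cums, offsets)):
            idx = np.searchsorted(cum, u[:, j], side="right").clip(0, len(cum) - 1)
            Z[np.arange(n_per_replicate), off + idx] = 1.0
        coords = (Z / n_vars) @ G / np.sqrt(lam)
        for p_idx, pair in enumerate(DIMENSION_PAIRS):
            sub = coords[:, list(pair)]
            m = sub.mean(axis=0)
            S = np.cov(sub, rowvar=False, ddof=1) / n_per_replicate
            diff = target[list(pair)] - m
            d2 = diff @ np.linalg.solve(S, diff)
            hits[p_idx] += d2 <= q
    per_pair = {pair: hits[i] / n_replicates for i, pair in enumerate(DIMENSION_PAIRS)}
    return {
        "per_pair": per_pair,
        "mean": float(np.mean(list(per_pair.values()))),
        "level": level,
        "n_replicates": n_replicates,
        "n_per_replicate": n_per_replicate,
    }


def population_barycenter(profile: ProfileSpec, framework) -> np.ndarray:
    """Expected map position of an evaluation drawn from ``profile``.

    Supplementary projection is linear in the fuzzy indicator row, so the
    expectation is simply the projection of the profile's concatenated
    category-probability vector.
    """
    row = profile.fuzzy_row()
    cols = pd.MultiIndex.from_tuples(profile.codebook.columns)
    frame = pd.DataFrame(row[None, :], columns=cols)
    return framework.project(frame)[0]
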