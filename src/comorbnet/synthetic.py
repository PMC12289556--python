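"""Synthetic claims cohorts with planted comorbidity structure.

Real all-payer claims databases sit behind data-use agreements, so every
downstream stage here is exercised on synthetic cohorts that emulate the
features the analysis depends on: per-code annual prevalences, planted
pairwise comorbidity strength expressed as odds ratios, record-level
demographics, and a mid-period utilization shock (a year in which chronic-care
claims dip and then rebound).

Dependence model
----------------
Correlated binary disease indicators are generated from a Gaussian
latent-threshold (copula) model: each patient-year draws a latent multivariate
normal vector with unit variances; code *j* is present when its latent
coordinate exceeds the ``Phi^{-1}(1 - prevalence_j)`` quantile.  The latent
correlation for a planted pair is solved numerically so that the implied 2x2
joint distribution has exactly the requested odds ratio
(:func:`solve_latent_correlation`).  Unplanted pairs default to latent
correlation zero, i.e. independence.

Disease *presence* and claim *emission* are separate layers: a present
condition emits a Poisson number of claims per year, and the yearly disruption
multiplier scales emission only — care delivery drops, the underlying disease
does not.
"""

from __future__ import annotations

import dataclasses
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .claims_io import ClaimsTable, normalize_icd10

__all__ = [
    "AssociationSpec",
    "SyntheticCohortConfig",
    "solve_latent_correlation",
    "planted_joint_probability",
    "sample_disease_indicators",
    "generate_claims",
    "generate_cohort",
]

_R_LIMIT = 1 - 1e-9  # keep the bivariate normal nonsingular


@dataclasses.dataclass(frozen=True)
class AssociationSpec:
    """A planted pairwise comorbidity: two codes and a target odds ratio."""

    code_a: str
    code_b: str
    target_odds_ratio: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "code_a", normalize_icd10(self.code_a))
        object.__setattr__(self, "code_b", normalize_icd10(self.code_b))
        if self.code_a == self.code_b:
            raise ValueError("association must link two distinct codes")
        if not self.target_odds_ratio > 0:
            raise ValueError("target odds ratio must be positive")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.code_a, self.code_b)))


@dataclasses.dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_patients : patients per cohort; each contributes one patient-year per
        calendar year in ``years``.
    prevalence : code → annual probability of the condition being present.
    associations : planted pairwise odds ratios; unplanted pairs independent.
    encounters_per_condition : mean claims emitted per present condition per
        year (Poisson), before any disruption multiplier.
    disruption : year → multiplier in (0, 1] on claim emission, modelling a
        utilization shock (e.g. ``{2022: 0.6}`` for a pandemic-year dip).
    age_mean, age_sd, female_fraction : demographic marginals; ages are drawn
        from a normal truncated to [0, 90] and held fixed across years.
    seed : master seed; a fixed seed makes the whole cohort bit-identical.
    """

    n_patients: int
    years: tuple[int, ...]
    prevalence: dict[str, float]
    associations: tuple[AssociationSpec, ...] = ()
    encounters_per_condition: float = 2.0
    disruption: dict[int, float] = dataclasses.field(default_factory=dict)
    age_mean: float = 53.8
    age_sd: float = 21.7
    female_fraction: float = 0.574
    seed: int = 0

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        self.prevalence = {normalize_icd10(c): float(p) for c, p in self.prevalence.items()}
        self.associations = tuple(
            a if isinstance(a, AssociationSpec) else AssociationSpec(**a)
            for a in self.associations
        )
        self.disruption = {int(y): float(m) for y, m in self.disruption.items()}
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not self.years:
            raise ValueError("at least one calendar year required")
        if not self.prevalence:
            raise ValueError("at least one code with a prevalence required")
        for code, p in self.prevalence.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence for {code} must be in (0, 1): {p}")
        seen: set[tuple[str, str]] = set()
        for assoc in self.associations:
            for code in (assoc.code_a, assoc.code_b):
                if code not in self.prevalence:
                    raise ValueError(f"association references unknown code {code}")
            if assoc.pair in seen:
                raise ValueError(f"duplicate association for pair {assoc.pair}")
            seen.add(assoc.pair)
        if self.encounters_per_condition < 0:
            raise ValueError("encounters_per_condition must be non-negative")
        for year, mult in self.disruption.items():
            if not 0 < mult <= 1:
                raise ValueError(f"disruption multiplier for {year} must be in (0, 1]")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(sorted(self.prevalence))

    def to_yaml(self, target: str | IO[str]) -> None:
        doc = {
            "n_patients": self.n_patients,
            "years": list(self.years),
            "prevalence": dict(self.prevalence),
            "associations": [
                {"code_a": a.code_a, "code_b": a.code_b, "target_odds_ratio": a.target_odds_ratio}
                for a in self.associations
            ],
            "encounters_per_condition": self.encounters_per_condition,
            "disruption": {int(y): m for y, m in self.disruption.items()},
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "female_fraction": self.female_fraction,
            "seed": self.seed,
        }
        text = yaml.safe_dump(doc, sort_keys=True)
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "w") as fh:
                fh.write(text)

    @classmethod
    def from_yaml(cls, source: str | IO[str]) -> "SyntheticCohortConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        return cls(**doc)


def planted_joint_probability(prev_a: float, prev_b: float, target_or: float) -> float:
    """P(both present) for two margins and an odds ratio (Plackett solution).

    For OR ≠ 1 the joint cell solves a quadratic; the root on the admissible
    branch is ``(S - sqrt(S^2 - 4·OR·(OR-1)·pa·pb)) / (2·(OR-1))`` with
    ``S = 1 + (pa+pb)(OR-1)``.  For OR = 1 it is simply ``pa·pb``.
    """
    if target_or == 1.0:
        return prev_a * prev_b
    s = 1 + (prev_a + prev_b) * (target_or - 1)
    disc = s * s - 4 * target_or * (target_or - 1) * prev_a * prev_b
    return (s - np.sqrt(disc)) / (2 * (target_or - 1))


def _joint_from_latent(prev_a: float, prev_b: float, r: float) -> float:
    """P(both present) under the latent-threshold model with correlation r."""
    za = stats.norm.ppf(1 - prev_a)
    zb = stats.norm.ppf(1 - prev_b)
    cov = [[1.0, r], [r, 1.0]]
    # P(X > za, Y > zb) via inclusion-exclusion on the bivariate CDF.
    cdf = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf(
        [za, zb]
    )
    return float(1 - (1 - prev_a) - (1 - prev_b) + cdf)


def solve_latent_correlation(
    prev_a: float, prev_b: float, target_or: float, tol: float = 1e-6
) -> float:
    """Latent normal correlation that plants a given odds ratio.

    Finds r in (-1, 1) such that thresholding a standard bivariate normal with
    correlation r at the (1 - prevalence) quantiles yields a 2x2 joint
    distribution whose odds ratio equals ``target_or`` (within ``tol`` on the
    joint-cell probability scale, solved by root finding on the
    bivariate-normal orthant probability).

    Raises
    ------
    ValueError
        If no correlation in (-1, 1) achieves the target, reporting the
        achievable odds-ratio range at these margins.
    """
    for name, p in (("prev_a", prev_a), ("prev_b", prev_b)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must be in (0, 1): {p}")
    if not target_or > 0:
        raise ValueError(f"target odds ratio must be positive: {target_or}")
    if target_or == 1.0:
        return 0.0

    p11_target = planted_joint_probability(prev_a, prev_b, target_or)
    lo = _joint_from_latent(prev_a, prev_b, -_R_LIMIT)
    hi = _joint_from_latent(prev_a, prev_b, _R_LIMIT)
    if not lo < p11_target < hi:

        def _or(p11: float) -> float:
            p10, p01 = prev_a - p11, prev_b - p11
            p00 = 1 - prev_a - prev_b + p11
            if p10 <= 0 or p01 <= 0:
                return np.inf
            return p11 * p00 / (p10 * p01)

        raise ValueError(
            f"odds ratio {target_or} unachievable at margins ({prev_a}, {prev_b}); "
            f"achievable range ≈ ({_or(lo):.4g}, {_or(hi):.4g})"
        )

    r = optimize.brentq(
        lambda r: _joint_from_latent(prev_a, prev_b, r) - p11_target,
        -_R_LIMIT,
        _R_LIMIT,
        xtol=1e-12,
        rtol=8.9e-16,
    )
    if abs(_joint_from_latent(prev_a, prev_b, r) - p11_target) > tol:
        raise ValueError("latent-correlation solver failed to reach tolerance")
    return float(r)


def latent_correlation_matrix(
    config: SyntheticCohortConfig, repair: bool = False
) -> np.ndarray:
    """Full latent correlation matrix implied by the planted associations.

    Unplanted pairs get latent correlation 0.  The completed matrix must be
    positive definite; with ``repair=True`` an indefinite matrix is projected
    to the nearest valid correlation matrix by clipping eigenvalues at 1e-8
    and rescaling the diagonal back to 1.
    """
    codes = config.codes
    index = {c: i for i, c in enumerate(codes)}
    R = np.eye(len(codes))
    for assoc in config.associations:
        r = solve_latent_correlation(
            config.prevalence[assoc.code_a],
            config.prevalence[assoc.code_b],
            assoc.target_odds_ratio,
        )
        i, j = index[assoc.code_a], index[assoc.code_b]
        R[i, j] = R[j, i] = r
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() <= 0:
        if not repair:
            pairs = sorted(a.pair for a in config.associations)
            raise ValueError(
                "implied latent correlation matrix is not positive definite "
                f"(min eigenvalue {eigvals.min():.3g}); planted pairs: {pairs}. "
                "Weaken the associations or pass repair=True."
            )
        vals, vecs = np.linalg.eigh(R)
        R = (vecs * np.clip(vals, 1e-8, None)) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def _patient_ids(n: int) -> np.ndarray:
    width = max(6, len(str(n)))
    return np.array([f"P{i:0{width}d}" for i in range(1, n + 1)])


def sample_disease_indicators(
    config: SyntheticCohortConfig, repair: bool = False
) -> pd.DataFrame:
    """Draw per-patient-year binary disease indicators from the latent model.

    Returns a 0/1 DataFrame indexed by (patient_id, year) with one column per
    code (sorted).  Presence is re-drawn independently each year given the
    prevalences; marginal frequencies converge to the configured prevalences
    and each planted pair's empirical odds ratio converges to its target.
    """
    R = latent_correlation_matrix(config, repair=repair)
    L = np.linalg.cholesky(R)
    codes = config.codes
    thresholds = stats.norm.ppf([1 - config.prevalence[c] for c in codes])

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    pids = _patient_ids(config.n_patients)
    blocks = []
    for year in config.years:
        latent = rng.standard_normal((config.n_patients, len(codes))) @ L.T
        blocks.append((latent > thresholds).astype(np.int8))
    frame = pd.DataFrame(
        np.vstack(blocks),
        index=pd.MultiIndex.from_arrays(
            [
                np.concatenate([pids] * len(config.years)),
                np.repeat(list(config.years), config.n_patients),
            ],
            names=["patient_id", "year"],
        ),
        columns=list(codes),
    )
    return frame


def generate_claims(
    indicators: pd.DataFrame, config: SyntheticCohortConfig
) -> ClaimsTable:
    """Emit a claims table from disease indicators.

    For each (patient, year, present code) a Poisson number of claims is drawn
    with mean ``encounters_per_condition × disruption.get(year, 1.0)``, each
    claim dated uniformly at random within the year and carrying that single
    code in the primary slot.  Demographics are sampled once per patient (age
    from a truncated normal on [0, 90], sex F with the configured female
    fraction, else M) and held fixed across years.  Deterministic under a
    fixed config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    pids = _patient_ids(config.n_patients)

    a = (0 - config.age_mean) / config.age_sd
    b = (90 - config.age_mean) / config.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd,
        size=config.n_patients, random_state=rng,
    )
    ages = np.clip(np.rint(ages), 0, 90).astype(int)
    sexes = np.where(rng.random(config.n_patients) < config.female_fraction, "F", "M")
    demo = {pid: (int(age), sex) for pid, age, sex in zip(pids, ages, sexes)}

    codes = np.asarray(indicators.columns)
    rows: list[tuple] = []
    for year in config.years:
        block = indicators.xs(year, level="year")
        lam = config.encounters_per_condition * config.disruption.get(year, 1.0)
        pat_idx, code_idx = np.nonzero(block.to_numpy())
        if len(pat_idx) == 0:
            continue
        n_claims = rng.poisson(lam, size=len(pat_idx))
        keep = n_claims > 0
        pat_rep = np.repeat(block.index.to_numpy()[pat_idx[keep]], n_claims[keep])
        code_rep = np.repeat(codes[code_idx[keep]], n_claims[keep])
        n_days = (pd.Timestamp(year + 1, 1, 1) - pd.Timestamp(year, 1, 1)).days
        offsets = rng.integers(0, n_days, size=len(pat_rep))
        dates = pd.Timestamp(year, 1, 1) + pd.to_timedelta(offsets, unit="D")
        for pid, code, date in zip(pat_rep, code_rep, dates):
            age, sex = demo[pid]
            rows.append((pid, date, (code,), age, sex))

    if not rows:
        raise ValueError(
            "synthetic cohort emitted no claims; raise encounters_per_condition "
            "or prevalences"
        )
    frame = pd.DataFrame(rows, columns=list(ClaimsTable.COLUMNS))
    frame["age"] = frame["age"].astype("Int64")
    frame = frame.sort_values(
        ["patient_id", "service_date", "dx"],
        key=lambda s: s.map(lambda v: v[0]) if s.name == "dx" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    span = (min(config.years), max(config.years))
    return ClaimsTable(frame, span=span)


def generate_cohort(
    config: SyntheticCohortConfig, repair: bool = False
) -> tuple[ClaimsTable, pd.DataFrame]:
    """Convenience wrapper: indicators plus the claims table they emit."""
    indicators = sample_disease_indicators(config, repair=repair)
    return generate_claims(indicators, config), indicators
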