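"""Synthetic cohort generation.

The method was developed on a 59-patient hemodialysis cohort that is
available only as per-feature summaries (mean +/- SD or yes/no counts) and
per-feature Pearson correlations with a binary stroke-risk group label
(25 low-risk / 34 high-risk). This module rebuilds a cohort with that
structure so the whole pipeline — standardization, the hyperplane
classifier, jackknife evaluation, the grid search — can be exercised
end to end.

Generation uses a single latent factor. With ``s`` the standardized 0/1
label and ``eps`` independent standard normal noise, each feature draws

    z = r * s + sqrt(1 - r^2) * eps

so ``corr(z, s) ~= r``. Continuous features are affinely mapped to the
target (mean, sd); binary features are thresholded at the empirical
quantile matching their positive proportion, which attenuates the realized
point-biserial correlation below ``|r|`` (documented, not corrected).
The label split is fixed (exactly ``n_positive`` positives), not Bernoulli,
because leave-one-out behavior depends on the realized class sizes.

:func:`generate_blobs` additionally provides two-Gaussian geometric
benchmarks for classifier sanity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .hyperplane import FeatureTable

__all__ = [
    "FeatureSpec",
    "CohortSpec",
    "default_cohort_spec",
    "generate_cohort",
    "generate_blobs",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Distributional target for one feature.

    Continuous features set ``mean`` and ``sd``; binary features set
    ``positive_proportion``. ``target_r`` is the desired Pearson
    correlation with the 0/1 group label, in (-1, 1).
    """

    name: str
    kind: str
    target_r: float
    mean: float | None = None
    sd: float | None = None
    positive_proportion: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise InputError(f"unknown feature kind {self.kind!r}")
        if not -1.0 < self.target_r < 1.0:
            raise InputError(f"target_r must lie in (-1, 1), got {self.target_r}")
        if self.kind == "continuous":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise InputError(f"continuous feature {self.name!r} needs mean and sd > 0")
            if self.positive_proportion is not None:
                raise InputError(f"continuous feature {self.name!r} must not set positive_proportion")
        else:
            if self.positive_proportion is None or not 0.0 < self.positive_proportion < 1.0:
                raise InputError(f"binary feature {self.name!r} needs positive_proportion in (0, 1)")
            if self.mean is not None or self.sd is not None:
                raise InputError(f"binary feature {self.name!r} must not set mean/sd")


@dataclass(frozen=True)
class CohortSpec:
    """A full cohort description: features, size, fixed label split, seed."""

    features: tuple[FeatureSpec, ...]
    n: int
    n_positive: int
    seed: int = 0
    clip_nonnegative: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        if self.n < 4:
            raise InputError(f"cohort size must be >= 4, got {self.n}")
        if not 0 < self.n_positive < self.n:
            raise InputError(f"n_positive must be in (0, n), got {self.n_positive}")


_N = 59  # reference cohort size


def _cont(name: str, mean: float, sd: float, r: float) -> FeatureSpec:
    return FeatureSpec(name=name, kind="continuous", mean=mean, sd=sd, target_r=r)


def _bin(name: str, positive: int, r: float) -> FeatureSpec:
    return FeatureSpec(name=name, kind="binary", positive_proportion=positive / _N, target_r=r)


#: per-feature summaries of the reference cohort: 32 predictors (clinical,
#: biochemical, nutritional and calcification variables plus the two stroke
#: scores); the 25/34 group split is the label.
_DEFAULT_FEATURES: tuple[FeatureSpec, ...] = (
    _bin("sex_male", 32, -0.0455),
    _cont("age", 55.83, 15.60, 0.4010),
    _bin("smoking", 1, -0.0847),
    _cont("bmi", 23.56, 3.12, 0.1639),
    _bin("dm", 24, 0.4847),
    _bin("cerebral_ischemia", 3, 0.0025),
    _bin("chd", 5, 0.0433),
    _cont("systolic_bp", 155.69, 23.63, -0.1150),
    _cont("diastolic_bp", 88.11, 13.71, -0.2043),
    _bin("phosphate_binder", 36, -0.2141),
    _cont("hemoglobin", 85.38, 18.12, -0.2584),
    _cont("crp", 11.74, 35.61, 0.3016),
    _cont("creatinine", 785.09, 368.62, -0.4252),
    _cont("glucose", 5.48, 2.28, 0.2608),
    _cont("calcium", 2.08, 0.24, 0.0520),
    _cont("phosphorus", 1.81, 0.38, -0.0862),
    _cont("triglycerides", 1.69, 1.08, -0.0542),
    _cont("cholesterol", 4.53, 1.42, -0.0466),
    _cont("ldl_c", 2.45, 0.96, -0.0252),
    _cont("hdl_c", 0.97, 0.55, 0.0866),
    _cont("hba1c", 5.82, 1.03, 0.2151),
    _cont("albumin", 34.31, 6.61, -0.1308),
    _cont("vitamin_d3", 7.86, 4.55, 0.3850),
    _cont("ipth", 274.50, 306.31, -0.0225),
    _cont("gnri", 96.06, 12.76, -0.0078),
    _cont("fgf23", 32.21, 53.02, -0.0966),
    _cont("klotho", 2.38, 2.33, 0.0443),
    _cont("il6", 25.37, 53.69, 0.2634),
    _cont("fetuin_a", 3.0320e5, 2.0606e5, -0.0234),
    _cont("aacs", 1.95, 1.55, 0.2113),
    _cont("chads2", 1.93, 1.11, 0.4247),
    _cont("cha2ds2_vasc", 2.79, 1.50, 0.5097),
)


def default_cohort_spec(seed: int = 0, n: int = _N, n_positive: int = 34) -> CohortSpec:
    """The reference-cohort specification: 32 mixed predictors, 59 patients, 25/34 split.

    ``n`` may be raised for larger Monte-Carlo draws; binary proportions
    stay as defined out of the 59-patient reference counts.
    """
    return CohortSpec(features=_DEFAULT_FEATURES, n=n, n_positive=n_positive, seed=seed)


def generate_cohort(spec: CohortSpec) -> FeatureTable:
    """Draw a cohort table from a :class:`CohortSpec`; pure function of the spec.

    With ``clip_nonnegative`` set, continuous draws are floored at 0 after
    the affine map (physiological supports); this truncation shifts the
    realized mean upward for features whose sd is comparable to the mean,
    so it is off by default.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    y = np.zeros(n, dtype=int)
    y[: spec.n_positive] = 1
    rng.shuffle(y)
    s = (y - y.mean()) / y.std()
    cols = []
    names = []
    kinds = []
    for f in spec.features:
        eps = rng.standard_normal(n)
        z = f.target_r * s + math.sqrt(1.0 - f.target_r**2) * eps
        if f.kind == "continuous":
            x = f.mean + f.sd * z
            if spec.clip_nonnegative:
                x = np.maximum(x, 0.0)
        else:
            thr = np.quantile(z, 1.0 - f.positive_proportion)
            x = (z > thr).astype(float)
        cols.append(x)
        names.append(f.name)
        kinds.append(f.kind)
    return FeatureTable(
        values=np.column_stack(cols),
        feature_names=names,
        feature_kinds=kinds,
        labels=y,
    )


def generate_blobs(
    n_per_class: int, dims: int, separation_sd: float, seed: int = 0
) -> FeatureTable:
    """Two unit-variance spherical Gaussian classes, centers ``separation_sd``
    standard deviations apart along the first axis."""
    if n_per_class < 2 or dims < 1:
        raise InputError("need n_per_class >= 2 and dims >= 1")
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal((n_per_class, dims))
    x1 = rng.standard_normal((n_per_class, dims))
    x1[:, 0] += separation_sd
    values = np.vstack([x0, x1])
    labels = np.repeat([0, 1], n_per_class)
    return FeatureTable(
        values=values,
        feature_names=[f"x{j}" for j in range(dims)],
        feature_kinds=["continuous"] * dims,
        labels=labels,
    )
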