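"""Fixed-effect pooling of per-study correlations and coefficient normalization.

The simulator's path coefficients come from a Hunter–Schmidt-style
meta-analysis of published correlations.  For a study reporting a sample
correlation ``r`` on ``n`` subjects, the large-sample variance of ``r`` is

    nu = (1 - r**2)**2 / (n - 1),

and the fixed-effect pooled estimate over k studies of the same causal path
is the inverse-variance weighted mean

    rho_hat = sum(r_i / nu_i) / sum(1 / nu_i),
    var(rho_hat) = 1 / sum(1 / nu_i),

with significance statistic Z = |rho_hat| / sqrt(var) and the usual normal
confidence interval rho_hat -+ z_{alpha/2} * sqrt(var).  Pooled estimates
are then normalized per dependent variable (coefficients of a variable's
parents rescaled to sum to 1 in absolute value) to serve as the
system-dynamics equation coefficients.

The model-fitting surface mirrors statsmodels: build a
:class:`CorrelationMetaAnalysis` from records, a DataFrame or a CSV, call
``fit()`` and read estimates off the returned :class:`MetaAnalysisResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import STRUCTURE, CoefficientSet

__all__ = [
    "EffectSizeRecord",
    "PathEstimate",
    "variance_of_r",
    "convert_to_r",
    "pool_correlations",
    "apply_reliability_correction",
    "normalize_coefficients",
    "generate_synthetic_effect_table",
    "CorrelationMetaAnalysis",
    "MetaAnalysisResults",
]

_EFFECT_KINDS = ("r", "t", "F", "beta")


@dataclass(frozen=True)
class EffectSizeRecord:
    """One study's effect size for one causal path.

    ``effect_kind`` is one of ``r`` (correlation), ``t``, ``F`` or ``beta``;
    ``df`` (denominator degrees of freedom) is required for t and F.
    """

    path_id: str
    study_id: str
    n: int
    effect_kind: str
    effect_value: float
    df: float | None = None

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"study {self.study_id}: sample size n must be >= 4, got {self.n}")
        if self.effect_kind not in _EFFECT_KINDS:
            raise ValueError(
                f"study {self.study_id}: effect_kind must be one of {_EFFECT_KINDS}, "
                f"got {self.effect_kind!r}"
            )
        if self.effect_kind == "r" and not -1 < self.effect_value < 1:
            raise ValueError(
                f"study {self.study_id}: correlation must lie in (-1, 1), got {self.effect_value}"
            )
        if self.effect_kind in ("t", "F") and self.df is None:
            raise ValueError(f"study {self.study_id}: {self.effect_kind}-statistics require df")
        if self.effect_kind == "F" and self.effect_value < 0:
            raise ValueError(f"study {self.study_id}: F must be nonnegative, got {self.effect_value}")


@dataclass(frozen=True)
class PathEstimate:
    """Pooled correlation for one causal path with variance, Z and CI."""

    path_id: str
    k: int
    n_total: int
    rho_hat: float
    var_rho_hat: float
    z_stat: float
    ci_low: float
    ci_high: float
    single_study: bool = False


def variance_of_r(r: float, n: int) -> float:
    """Large-sample variance of a sample correlation: (1 - r**2)**2 / (n - 1)."""
    if not -1 < r < 1:
        raise ValueError(f"correlation must lie in (-1, 1), got {r}")
    if n < 2:
        raise ValueError(f"sample size must be >= 2, got {n}")
    return (1.0 - r * r) ** 2 / (n - 1)


def convert_to_r(record: EffectSizeRecord) -> float:
    """Convert a study's effect size to a correlation.

    t-statistics map to r = t / sqrt(t**2 + df); F-statistics (numerator
    df assumed 1) to r = sqrt(F / (F + df)).  Standardized regression
    coefficients (beta) have no exact conversion and are passed through
    with a warning — see the methods note for the alternatives considered.
    """
    kind, v = record.effect_kind, record.effect_value
    if kind == "r":
        return v
    if kind == "t":
        return v / math.sqrt(v * v + record.df)
    if kind == "F":
        return math.sqrt(v / (v + record.df))
    warnings.warn(
        f"study {record.study_id}: beta coefficient {v} used as r without conversion",
        stacklevel=2,
    )
    return v


def apply_reliability_correction(r: float, rxx: float, ryy: float) -> float:
    """Attenuation correction r / sqrt(rxx * ryy), clipped into (-1, 1).

    Off by default in the pooling pipeline: the published corrected
    correlations are consumed as given inputs rather than recomputed.
    """
    if not (0 < rxx <= 1 and 0 < ryy <= 1):
        raise ValueError(f"reliabilities must lie in (0, 1], got rxx={rxx}, ryy={ryy}")
    rc = r / math.sqrt(rxx * ryy)
    limit = 1.0 - 1e-12
    if abs(rc) >= 1:
        warnings.warn(
            f"reliability-corrected correlation {rc:.4f} exceeds 1 in magnitude; clipped",
            stacklevel=2,
        )
        rc = math.copysign(limit, rc)
    return rc


def pool_correlations(
    records: Sequence[EffectSizeRecord], alpha: float = 0.05
) -> PathEstimate:
    """Fixed-effect inverse-variance pooling of one path's correlations.

    All records must share a ``path_id``; non-r effect sizes are converted
    first.  A single-study path is valid: the estimate equals the study's r
    (variance from the large-sample formula) and is flagged ``single_study``.
    """
    if len(records) == 0:
        raise ValueError("cannot pool an empty record list")
    path_ids = {rec.path_id for rec in records}
    if len(path_ids) != 1:
        raise ValueError(f"records mix several paths: {sorted(path_ids)}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")

    rs = np.array([convert_to_r(rec) for rec in records])
    ns = np.array([rec.n for rec in records])
    nus = np.array([variance_of_r(r, n) for r, n in zip(rs, ns)])
    weights = 1.0 / nus

    rho_hat = float(np.sum(weights * rs) / np.sum(weights))
    var = float(1.0 / np.sum(weights))
    z = abs(rho_hat) / math.sqrt(var)
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z_crit * math.sqrt(var)
    return PathEstimate(
        path_id=path_ids.pop(),
        k=len(records),
        n_total=int(ns.sum()),
        rho_hat=rho_hat,
        var_rho_hat=var,
        z_stat=z,
        ci_low=rho_hat - half,
        ci_high=rho_hat + half,
        single_study=len(records) == 1,
    )


def normalize_coefficients(
    estimates: Iterable[PathEstimate] | Mapping[str, float],
    structure: Mapping[str, Sequence[str]] = STRUCTURE,
) -> dict[str, float]:
    """Rescale pooled path estimates into simulator coefficients.

    For a dependent variable with a single parent the pooled estimate passes
    through unchanged; with several parents each coefficient is
    |rho_i| / sum_j |rho_j| with the original sign re-attached, so the
    parents of every dependent variable sum to 1 in absolute value.
    """
    if isinstance(estimates, Mapping):
        by_path = dict(estimates)
    else:
        by_path = {e.path_id: e.rho_hat for e in estimates}
    out: dict[str, float] = {}
    for dep, parents in structure.items():
        missing = [p for p in parents if p not in by_path]
        if missing:
            raise ValueError(f"dependent variable {dep}: missing parent estimate(s) {missing}")
        if len(parents) == 1:
            out[parents[0]] = by_path[parents[0]]
            continue
        total = sum(abs(by_path[p]) for p in parents)
        if total == 0:
            raise ValueError(f"dependent variable {dep}: all parent estimates are zero")
        for p in parents:
            rho = by_path[p]
            out[p] = math.copysign(abs(rho) / total, rho) if rho != 0 else 0.0
    return out


def generate_synthetic_effect_table(
    true_rho_by_path: Mapping[str, float],
    k_per_path: int,
    n_per_study: int,
    seed: int,
) -> list[EffectSizeRecord]:
    """Draw a synthetic coded effect-size table for parameter-recovery tests.

    Each path gets ``k_per_path`` sample correlations from the large-sample
    normal approximation r ~ N(rho, (1 - rho**2)**2 / (n - 1)), clipped into
    the open interval (-1, 1).  Deterministic given ``seed``.
    """
    if k_per_path < 2 or n_per_study < 2:
        raise ValueError("k_per_path and n_per_study must both be >= 2")
    for path, rho in true_rho_by_path.items():
        if not -1 < rho < 1:
            raise ValueError(f"path {path}: true correlation must lie in (-1, 1), got {rho}")
    rng = np.random.default_rng(seed)
    limit = 1.0 - 1e-12
    records = []
    for path, rho in true_rho_by_path.items():
        sd = (1.0 - rho * rho) / math.sqrt(n_per_study - 1)
        draws = np.clip(rng.normal(rho, sd, size=k_per_path), -limit, limit)
        for i, r in enumerate(draws):
            records.append(
                EffectSizeRecord(
                    path_id=path,
                    study_id=f"{path}/synth{i:03d}",
                    n=n_per_study,
                    effect_kind="r",
                    effect_value=float(r),
                )
            )
    return records


class CorrelationMetaAnalysis:
    """Fixed-effect meta-analysis model over a coded effect-size table.

    Parameters
    ----------
    records : sequence of EffectSizeRecord
        The coded table; records are grouped by ``path_id`` and pooled per
        path by :func:`pool_correlations`.

    Examples
    --------
    >>> from dualsafe.datasets import load_builtin_fixture
    >>> model = CorrelationMetaAnalysis(load_builtin_fixture("table1_effects"))
    >>> res = model.fit()
    >>> round(res.estimates["PH->USPH"].rho_hat, 3)  # doctest: +SKIP
    0.644
    """

    def __init__(self, records: Sequence[EffectSizeRecord]):
        if len(records) == 0:
            raise ValueError("effect-size table is empty")
        self.records = list(records)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CorrelationMetaAnalysis":
        """Build from a DataFrame with the coded-table columns
        ``path_id, study_id, n, effect_kind, effect_value[, df]``."""
        records = []
        for row in df.itertuples(index=False):
            df_val = getattr(row, "df", None)
            if df_val is not None and pd.isna(df_val):
                df_val = None
            records.append(
                EffectSizeRecord(
                    path_id=str(row.path_id),
                    study_id=str(row.study_id),
                    n=int(row.n),
                    effect_kind=str(row.effect_kind),
                    effect_value=float(row.effect_value),
                    df=None if df_val is None else float(df_val),
                )
            )
        return cls(records)

    @classmethod
    def from_csv(cls, path) -> "CorrelationMetaAnalysis":
        return cls.from_dataframe(pd.read_csv(path))

    def fit(self, alpha: float = 0.05) -> "MetaAnalysisResults":
        """Pool every path in the table; returns a results object."""
        groups: dict[str, list[EffectSizeRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.path_id, []).append(rec)
        estimates = {
            path: pool_correlations(recs, alpha=alpha) for path, recs in groups.items()
        }
        return MetaAnalysisResults(self, estimates, alpha)


class MetaAnalysisResults:
    """Pooled path estimates with a tabular and printable summary."""

    def __init__(
        self,
        model: CorrelationMetaAnalysis,
        estimates: Mapping[str, PathEstimate],
        alpha: float,
    ):
        self.model = model
        self.estimates = dict(estimates)
        self.alpha = alpha

    @property
    def table(self) -> pd.DataFrame:
        """One row per path: k, n_total, rho_hat, var, z, CI, single-study flag."""
        rows = [
            {
                "path_id": e.path_id,
                "k": e.k,
                "n_total": e.n_total,
                "rho_hat": e.rho_hat,
                "var": e.var_rho_hat,
                "z": e.z_stat,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "single_study": e.single_study,
            }
            for e in self.estimates.values()
        ]
        return pd.DataFrame(rows)

    def normalized(
        self, structure: Mapping[str, Sequence[str]] = STRUCTURE
    ) -> dict[str, float]:
        """Normalized simulator coefficients per dependent variable."""
        return normalize_coefficients(self.estimates.values(), structure)

    def coefficient_set(
        self, structure: Mapping[str, Sequence[str]] = STRUCTURE
    ) -> CoefficientSet:
        """Normalized coefficients packed into a validated CoefficientSet."""
        return CoefficientSet(self.normalized(structure))

    def summary(self) -> str:
        """Human-readable pooling report; single-study paths carry a '*'."""
        df = self.table.copy()
        df["flag"] = np.where(df["single_study"], "*", "")
        cols = ["path_id", "k", "n_total", "rho_hat", "z", "ci_low", "ci_high", "flag"]
        header = (
            f"Fixed-effect correlation pooling ({len(df)} paths, "
            f"alpha={self.alpha:g})\n"
        )
        body = df[cols].to_string(index=False, float_format=lambda x: f"{x:8.4f}")
        note = "\n* single-study path: estimate is the study's own r"
        return header + body + (note if df["single_study"].any() else "")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<MetaAnalysisResults: {len(self.estimates)} paths>"
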