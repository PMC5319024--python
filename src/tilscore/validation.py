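"""Cross-platform concordance and technical reproducibility statistics.

Concordance between expression-derived cell scores and an orthogonal
platform (flow cytometry, IHC) is summarized by Pearson correlation, the
slope of the least-squares fit (near-unit slopes mean a doubling on one
platform predicts a doubling on the other), and a mean-centered RMSE:
because each platform reports on its own scale, both measurement sets are
centered before differencing.

Technical reproducibility of a cell score over replicate assays is
summarized by a one-way random-effects decomposition (sample as random
effect, REML): the proportion of variance due to noise is the residual
variance over residual plus between-sample variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchedMeasurements",
    "VarianceComponents",
    "centered_rmse",
    "platform_correlation",
    "noise_variance",
    "ReproducibilityModel",
    "ReproducibilityResults",
]


@dataclass
class MatchedMeasurements:
    """Two aligned log2-scale measurement vectors from different platforms."""

    sample_ids: list[str]
    platform_a: np.ndarray
    platform_b: np.ndarray
    labels: tuple[str, str] = ("platform_a", "platform_b")

    def __post_init__(self) -> None:
        self.platform_a = np.asarray(self.platform_a, dtype=float)
        self.platform_b = np.asarray(self.platform_b, dtype=float)
        if not (
            len(self.sample_ids) == self.platform_a.size == self.platform_b.size
        ):
            raise ValueError("sample_ids and both platforms must be aligned")


def _pair_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, MatchedMeasurements):
        return pairs.platform_a, pairs.platform_b
    a, b = pairs
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("measurement vectors must have equal length")
    return a, b


def centered_rmse(pairs) -> float:
    """RMSE between two platforms after mean-centering each separately.

    Centering removes the per-platform scale offset, so the statistic
    reflects disagreement in relative (fold-change) terms only.
    """
    a, b = _pair_arrays(pairs)
    if a.size < 2:
        raise ValueError("need at least 2 matched pairs")
    d = (a - a.mean()) - (b - b.mean())
    return float(np.sqrt(np.mean(d**2)))


def platform_correlation(pairs) -> tuple[float, float]:
    """Pearson r between platforms and the least-squares slope (b on a)."""
    a, b = _pair_arrays(pairs)
    if a.size < 3:
        raise ValueError("need at least 3 matched pairs")
    if np.var(a) == 0.0 or np.var(b) == 0.0:
        raise ValueError("zero variance in one platform's measurements")
    r = float(stats.pearsonr(a, b).statistic)
    slope = float(np.cov(a, b, ddof=1)[0, 1] / np.var(a, ddof=1))
    return r, slope


@dataclass
class VarianceComponents:
    """One-way random-effects variance decomposition of replicate scores."""

    between_sample_variance: float
    residual_variance: float
    n_samples: int
    n_replicates_per_sample: float
    truncated: bool = False  # negative between-sample estimate clipped to 0

    def __post_init__(self) -> None:
        if self.between_sample_variance < 0 or self.residual_variance < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def noise_proportion(self) -> float:
        """Residual / (residual + between); 0 when both variances vanish."""
        total = self.residual_variance + self.between_sample_variance
        if total == 0.0:
            return 0.0
        return self.residual_variance / total

    @property
    def noise_sd(self) -> float:
        """Residual SD on the log2 scale (technical noise SD)."""
        return float(np.sqrt(self.residual_variance))


def _to_long(scores) -> pd.DataFrame:
    """Normalize replicate input to a long frame with sample/value columns."""
    if isinstance(scores, pd.DataFrame):
        df = scores[["sample", "value"]].copy()
    elif isinstance(scores, Mapping):
        rows = [
            {"sample": s, "value": float(v)}
            for s, reps in scores.items()
            for v in reps
        ]
        df = pd.DataFrame(rows)
    else:
        raise TypeError("scores must be a mapping sample -> replicates or a DataFrame")
    if df.empty:
        raise ValueError("no replicate measurements supplied")
    return df


def noise_variance(scores) -> VarianceComponents:
    """Estimate between-sample and residual variance of replicate cell scores.

    Fits a linear mixed model with a random intercept per sample by REML
    (statsmodels MixedLM), handling unbalanced replication; on balanced data
    the estimates agree with the one-way ANOVA method-of-moments closed form
    whenever that estimate is non-negative.  Negative between-sample
    estimates are truncated at zero and flagged.

    Parameters
    ----------
    scores : mapping sample_id -> list of replicate score values, or a long
        DataFrame with columns ``sample`` and ``value``.
    """
    df = _to_long(scores)
    counts = df.groupby("sample").size()
    if len(counts) < 2:
        raise ValueError("need at least 2 samples")
    if (counts < 2).all():
        raise ValueError("no replication: every sample has a single measurement")

    y = df["value"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return VarianceComponents(0.0, 0.0, len(counts), float(counts.mean()))

    import statsmodels.api as sm

    groups = df["sample"].to_numpy()
    exog = np.ones((len(df), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=groups)
        # powell converges the profiled REML objective well past the
        # precision at which balanced-design estimates match the ANOVA
        # closed form
        res = model.fit(reml=True, method="powell")
    resid_var = float(res.scale)
    between = float(np.asarray(res.cov_re).ravel()[0])
    truncated = between < 0
    between = max(between, 0.0)
    return VarianceComponents(
        between_sample_variance=between,
        residual_variance=resid_var,
        n_samples=int(len(counts)),
        n_replicates_per_sample=float(counts.mean()),
        truncated=truncated,
    )


class ReproducibilityModel:
    """Replicate-based reproducibility of cell scores, one model per column.

    Parameters
    ----------
    scores : DataFrame
        Rows are replicate assays; one column per cell type plus a
        ``sample`` column (or a separate ``sample_ids`` vector) mapping each
        replicate row to its biological sample.
    """

    def __init__(self, scores: pd.DataFrame, sample_ids: Sequence[str] | None = None):
        scores = scores.copy()
        if sample_ids is not None:
            scores["sample"] = list(sample_ids)
        if "sample" not in scores.columns:
            raise ValueError("provide a 'sample' column or sample_ids")
        self.scores = scores

    def fit(self) -> "ReproducibilityResults":
        components = {}
        for col in self.scores.columns:
            if col == "sample":
                continue
            long = pd.DataFrame(
                {"sample": self.scores["sample"], "value": self.scores[col]}
            )
            components[col] = noise_variance(long)
        return ReproducibilityResults(self, components)


class ReproducibilityResults:
    """Per-cell-type variance components and noise proportions."""

    def __init__(self, model, components: dict[str, VarianceComponents]):
        self.model = model
        self.components = components

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "cell_type": name,
                "noise_sd_log2": vc.noise_sd,
                "noise_proportion": vc.noise_proportion,
                "between_sample_variance": vc.between_sample_variance,
                "residual_variance": vc.residual_variance,
                "n_samples": vc.n_samples,
                "mean_replicates": vc.n_replicates_per_sample,
            }
            for name, vc in self.components.items()
        ]
        return pd.DataFrame(rows).set_index("cell_type")
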