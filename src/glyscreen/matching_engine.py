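"""Propensity estimation, nearest-neighbor matching with replacement, and
covariate-balance diagnostics.

For one drug class the engine (1) fits an exposure-propensity logistic model
on the configured covariate summaries (standardized internally), (2) pairs
every exposed patient with the unexposed patient of closest propensity
score, with replacement (a control may serve several treated patients), and
(3) judges the match by the control-reuse ("resampling") rate and per-feature
two-sample Kolmogorov–Smirnov tests, excluding the class when reuse exceeds
the limit or any feature remains detectably imbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_builder import DEFAULT_FEATURES, EXPOSURE_PREFIX
from .errors import GlyscreenError, ValidationError
from .stats_core import fit_logistic, predict_probability

__all__ = [
    "MatchConfig",
    "MatchResult",
    "BalanceReport",
    "propensity_scores",
    "match_with_replacement",
    "assess_balance",
    "feature_ks",
]


@dataclass(frozen=True)
class MatchConfig:
    """Matching and exclusion-rule settings.

    ``resampling_rate_limit``: maximum tolerated control reuse (default 20%).
    ``ks_p_exclusion_threshold``: a feature whose post-match KS p-value falls
    below this marks the match as failed (default 0.001) — small p means the
    matched arms still differ on that covariate.
    """

    caliper: float | None = None
    resampling_rate_limit: float = 0.20
    ks_p_exclusion_threshold: float = 0.001
    features: tuple = DEFAULT_FEATURES

    def __post_init__(self) -> None:
        if not 0.0 <= self.resampling_rate_limit <= 1.0:
            raise ValidationError("resampling_rate_limit must lie in [0, 1]")
        if not 0.0 < self.ks_p_exclusion_threshold < 1.0:
            raise ValidationError("ks_p_exclusion_threshold must lie in (0, 1)")
        if self.caliper is not None and self.caliper <= 0:
            raise ValidationError("caliper must be positive when set")


@dataclass
class MatchResult:
    """Treated/control pairing for one drug class.

    ``pairs`` holds (treated_id, control_id, |score difference|) with every
    treated id at most once; control ids may repeat. ``resampling_rate`` is
    1 - unique controls / number of pairs.
    """

    drug_class: str
    pairs: list
    treated_scores: pd.Series
    control_scores: pd.Series
    resampling_rate: float
    n_treated: int
    n_control_unique: int
    n_dropped_caliper: int = 0


@dataclass
class BalanceReport:
    """Per-feature KS diagnostics and the keep/exclude verdict for one match."""

    ks: dict  # feature -> (statistic, p_value)
    resampling_rate: float
    verdict: str  # "keep" or "exclude"
    reasons: list = field(default_factory=list)
    pre_match_ks: dict | None = None


def propensity_scores(
    cohort: pd.DataFrame, drug_class: str, features=None
) -> pd.Series:
    """Exposure-propensity score for every cohort patient.

    Fits exposure-to-``drug_class`` on the standardized feature columns by
    maximum-likelihood logistic regression; zero-variance columns are dropped
    before fitting. Returns P(exposed | covariates) indexed like the cohort.
    """
    features = list(features or DEFAULT_FEATURES)
    col = EXPOSURE_PREFIX + drug_class
    if col not in cohort.columns:
        raise ValidationError(f"unknown drug class {drug_class!r}")
    missing = [f for f in features if f not in cohort.columns]
    if missing:
        raise GlyscreenError(f"features missing from cohort: {missing}")
    y = cohort[col].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValidationError(
            f"cannot match {drug_class!r}: no contrast in exposure"
        )
    X = cohort[features].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    model = fit_logistic(Xs, y)
    scores = predict_probability(model, Xs)
    return pd.Series(scores, index=cohort.index, name=f"ps_{drug_class}")


def match_with_replacement(
    treated_scores: pd.Series,
    control_scores: pd.Series,
    config: MatchConfig | None = None,
    drug_class: str = "",
) -> MatchResult:
    """Pair each treated patient with the control of closest propensity score.

    Replacement is allowed. Ties — several controls equally close — resolve
    to the smallest control id, making the matching deterministic and
    invariant to presentation order. With a caliper set, treated patients
    with no control within it are dropped and counted.
    """
    config = config or MatchConfig()
    if len(treated_scores) == 0 or len(control_scores) == 0:
        raise ValidationError("both treated and control groups must be non-empty")

    ctrl = control_scores.sort_index()
    order = np.argsort(ctrl.to_numpy(), kind="mergesort")  # stable: id order within ties
    c_scores = ctrl.to_numpy()[order]
    c_ids = ctrl.index.to_numpy()[order]
    # one candidate per distinct score: the smallest id (first under stable sort)
    distinct = np.ones(c_scores.size, dtype=bool)
    distinct[1:] = c_scores[1:] != c_scores[:-1]
    c_scores = c_scores[distinct]
    c_ids = c_ids[distinct]

    t = treated_scores.sort_index()
    t_scores = t.to_numpy()
    pos = np.searchsorted(c_scores, t_scores)
    left = np.clip(pos - 1, 0, c_scores.size - 1)
    right = np.clip(pos, 0, c_scores.size - 1)
    dl = np.abs(t_scores - c_scores[left])
    dr = np.abs(c_scores[right] - t_scores)
    use_left = (dl < dr) | ((dl == dr) & (c_ids[left] <= c_ids[right]))
    chosen = np.where(use_left, left, right)
    dist = np.where(use_left, dl, dr)

    pairs = []
    n_dropped = 0
    for tid, d, j in zip(t.index.to_numpy(), dist, chosen):
        if config.caliper is not None and d > config.caliper:
            n_dropped += 1
            continue
        pairs.append((tid, c_ids[j], float(d)))
    if not pairs:
        raise ValidationError("caliper left no matched pairs")
    n_unique = len({cid for _, cid, _ in pairs})
    rate = 1.0 - n_unique / len(pairs)
    return MatchResult(
        drug_class=drug_class,
        pairs=pairs,
        treated_scores=treated_scores,
        control_scores=control_scores,
        resampling_rate=rate,
        n_treated=len(pairs),
        n_control_unique=n_unique,
        n_dropped_caliper=n_dropped,
    )


def feature_ks(cohort: pd.DataFrame, treated_ids, control_ids, features) -> dict:
    """Two-sample KS per feature between two id lists (repeats respected)."""
    from .stats_core import ks_two_sample

    missing = [f for f in features if f not in cohort.columns]
    if missing:
        raise GlyscreenError(f"feature {missing[0]!r} missing from cohort")
    ti = cohort.index.get_indexer(np.asarray(list(treated_ids)))
    ci = cohort.index.get_indexer(np.asarray(list(control_ids)))
    if (ti < 0).any() or (ci < 0).any():
        raise GlyscreenError("matched ids not present in cohort")
    out = {}
    for feat in features:
        col = cohort[feat].to_numpy(dtype=float)
        r = ks_two_sample(col[ti], col[ci])
        out[feat] = (r.statistic, r.p_value)
    return out


def assess_balance(
    matched: MatchResult, cohort: pd.DataFrame, config: MatchConfig | None = None
) -> BalanceReport:
    """Judge one match by control reuse and per-feature KS balance.

    Matched controls enter the KS samples once per pair (a control reused k
    times contributes k copies). The class is excluded when the resampling
    rate exceeds the limit or any feature's KS p-value falls below the
    exclusion threshold; reasons list every rule that fired. KS on tied
    (discrete) features is computed on the data as-is, which is conservative.
    """
    config = config or MatchConfig()
    if not matched.pairs:
        raise ValidationError("assess_balance requires a non-empty match")
    t_ids = [p[0] for p in matched.pairs]
    c_ids = [p[1] for p in matched.pairs]
    ks = feature_ks(cohort, t_ids, c_ids, config.features)

    reasons = []
    if matched.resampling_rate > config.resampling_rate_limit:
        reasons.append(
            f"resampling rate {matched.resampling_rate:.3f} exceeds limit "
            f"{config.resampling_rate_limit:.3f}"
        )
    for feat, (d, p) in ks.items():
        if p < config.ks_p_exclusion_threshold:
            reasons.append(
                f"KS imbalance on {feat}: p={p:.2e} < "
                f"{config.ks_p_exclusion_threshold:g} (D={d:.4f})"
            )
    return BalanceReport(
        ks=ks,
        resampling_rate=matched.resampling_rate,
        verdict="exclude" if reasons else "keep",
        reasons=reasons,
    )
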