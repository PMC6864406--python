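"""Exhaustive per-drug-class screen with Bonferroni control.

For every eligible concomitant drug class (>= min_group_size exposed
patients) the screen fits an exposure propensity model, matches exposed to
unexposed with replacement, checks balance, tabulates glycemic-control
success for treated vs matched controls in a 2x2 table, and applies the
uncorrected Pearson chi-squared test. Raw p-values are Bonferroni-corrected
by the number of classes actually tested. Classes failing the balance or
resampling rules are still tabulated for audit but flagged and kept out of
the findings section.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_builder import CohortCriteria, eligible_drug_classes, EXPOSURE_PREFIX
from .errors import DegenerateTableError, ValidationError
from .matching_engine import (
    BalanceReport,
    MatchConfig,
    assess_balance,
    feature_ks,
    match_with_replacement,
    propensity_scores,
)
from .stats_core import Table2x2, bonferroni, chi2_2x2

__all__ = ["ScreenConfig", "ScreenResult", "screen_all", "compare_fixed_groups", "write_report"]


@dataclass(frozen=True)
class ScreenConfig:
    criteria: CohortCriteria = field(default_factory=CohortCriteria)
    match: MatchConfig = field(default_factory=MatchConfig)
    top_k: int = 5
    alpha: float = 0.05
    seed: int = 0
    subgroup_antidiabetic_class: str | None = None
    continuity_correction: bool = False
    #: sensitivity analysis: McNemar's test on discordant matched pairs
    #: instead of Pearson on the expanded table
    use_mcnemar: bool = False

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass
class ScreenResult:
    """Full test record for one drug class (or one fixed two-group comparison)."""

    drug_class: str
    n_treated: int
    n_control: int
    n_control_unique: int
    success_rate_treated: float
    success_rate_control: float
    table: Table2x2
    chi2_statistic: float
    p_raw: float
    p_bonferroni: float
    excluded: bool = False
    exclusion_reasons: list = field(default_factory=list)
    balance: BalanceReport | None = None


def mcnemar_pairs(y_treated, y_control):
    """McNemar's test on matched-pair outcomes: (n10 - n01)^2 / (n10 + n01)
    over the discordant pairs, df = 1. Respects the pairing that the
    default Pearson test ignores; offered as a sensitivity analysis."""
    from scipy.stats import chi2 as _chi2

    from .stats_core import TestResult

    yt = np.asarray(y_treated, dtype=int)
    yc = np.asarray(y_control, dtype=int)
    if yt.size != yc.size or yt.size == 0:
        raise ValidationError("McNemar requires equal-length, non-empty pair outcomes")
    n10 = int(np.sum((yt == 1) & (yc == 0)))
    n01 = int(np.sum((yt == 0) & (yc == 1)))
    if n10 + n01 == 0:
        raise DegenerateTableError("no discordant pairs: McNemar statistic undefined")
    stat = (n10 - n01) ** 2 / (n10 + n01)
    return TestResult(
        statistic=float(stat),
        p_value=float(_chi2.sf(stat, df=1)),
        df=1,
        method="mcnemar-pairs",
    )


def screen_all(cohort: pd.DataFrame, config: ScreenConfig | None = None) -> list:
    """Run the exhaustive matched screen over every eligible drug class.

    Returns one :class:`ScreenResult` per tested class, sorted by ascending
    raw p-value (ties by class code). The Bonferroni multiplier is the
    number of classes tested, regardless of how many survive exclusion.
    Deterministic: matching has no random element, so reruns on the same
    cohort are identical.
    """
    config = config or ScreenConfig()
    if cohort.empty:
        raise ValidationError("nothing to screen: empty cohort")
    if config.subgroup_antidiabetic_class is not None:
        cohort = cohort[cohort["antidiabetic_class"] == config.subgroup_antidiabetic_class]
        if cohort.empty:
            raise ValidationError(
                f"nothing to screen: no patients on {config.subgroup_antidiabetic_class!r}"
            )
    classes = eligible_drug_classes(cohort, config.criteria)
    if not classes:
        raise ValidationError("nothing to screen: no eligible drug classes")

    outcome = cohort["outcome"].to_numpy(dtype=int)
    pos = {pid: i for i, pid in enumerate(cohort.index)}
    results = []
    for cls in classes:
        scores = propensity_scores(cohort, cls, config.match.features)
        exposed = cohort[EXPOSURE_PREFIX + cls].to_numpy(dtype=bool)
        matched = match_with_replacement(
            scores[exposed], scores[~exposed], config.match, drug_class=cls
        )
        report = assess_balance(matched, cohort, config.match)
        t_ids = [p[0] for p in matched.pairs]
        c_ids = [p[1] for p in matched.pairs]
        report.pre_match_ks = feature_ks(
            cohort, cohort.index[exposed], cohort.index[~exposed], config.match.features
        )
        y_t = outcome[[pos[i] for i in t_ids]]
        y_c = outcome[[pos[i] for i in c_ids]]
        a, b = int(y_t.sum()), int(len(y_t) - y_t.sum())
        c, d = int(y_c.sum()), int(len(y_c) - y_c.sum())
        table = Table2x2(a, b, c, d)
        excluded = report.verdict == "exclude"
        reasons = list(report.reasons)
        try:
            if config.use_mcnemar:
                test = mcnemar_pairs(y_t, y_c)
            else:
                test = chi2_2x2(table, config.continuity_correction)
            stat, p_raw = test.statistic, test.p_value
        except DegenerateTableError:
            stat, p_raw = float("nan"), float("nan")
            excluded = True
            reasons.append("degenerate 2x2 table: a success/failure margin is zero")
        results.append(
            ScreenResult(
                drug_class=cls,
                n_treated=len(t_ids),
                n_control=len(c_ids),
                n_control_unique=matched.n_control_unique,
                success_rate_treated=a / max(1, a + b),
                success_rate_control=c / max(1, c + d),
                table=table,
                chi2_statistic=stat,
                p_raw=p_raw,
                p_bonferroni=float("nan"),
                excluded=excluded,
                exclusion_reasons=reasons,
                balance=report,
            )
        )

    m = len(classes)
    finite = [r for r in results if np.isfinite(r.p_raw)]
    adjusted = bonferroni([r.p_raw for r in finite])
    for r, p_adj in zip(finite, adjusted):
        r.p_bonferroni = p_adj
    results.sort(key=lambda r: (not np.isfinite(r.p_raw), r.p_raw, r.drug_class))
    for r in results:
        r.exclusion_reasons = r.exclusion_reasons  # keep list type stable
    return results


def compare_fixed_groups(group_a, group_b, label: str = "fixed-comparison") -> ScreenResult:
    """Single pre-specified comparison of two outcome vectors (no matching,
    no multiplicity correction).

    ``group_a`` / ``group_b`` are iterables of binary outcomes
    (1=success). Builds the 2x2 table with group_a as the exposed row and
    runs the uncorrected Pearson chi-squared test.
    """
    ya = np.asarray(list(group_a), dtype=int)
    yb = np.asarray(list(group_b), dtype=int)
    if ya.size == 0 or yb.size == 0:
        raise ValidationError("both groups must be non-empty")
    table = Table2x2(int(ya.sum()), int(ya.size - ya.sum()), int(yb.sum()), int(yb.size - yb.sum()))
    try:
        test = chi2_2x2(table)
    except DegenerateTableError as err:
        raise DegenerateTableError(
            f"fixed-group comparison {label!r}: {err}"
        ) from err
    return ScreenResult(
        drug_class=label,
        n_treated=int(ya.size),
        n_control=int(yb.size),
        n_control_unique=int(yb.size),
        success_rate_treated=float(ya.mean()),
        success_rate_control=float(yb.mean()),
        table=table,
        chi2_statistic=test.statistic,
        p_raw=test.p_value,
        p_bonferroni=test.p_value,
    )


_CSV_FIELDS = [
    "drug_class",
    "n_treated",
    "n_control",
    "n_control_unique",
    "success_rate_treated",
    "success_rate_control",
    "a",
    "b",
    "c",
    "d",
    "chi2_statistic",
    "p_raw",
    "p_bonferroni",
    "excluded",
    "exclusion_reasons",
]


def _flat(r: ScreenResult) -> dict:
    return {
        "drug_class": r.drug_class,
        "n_treated": r.n_treated,
        "n_control": r.n_control,
        "n_control_unique": r.n_control_unique,
        "success_rate_treated": r.success_rate_treated,
        "success_rate_control": r.success_rate_control,
        "a": r.table.a,
        "b": r.table.b,
        "c": r.table.c,
        "d": r.table.d,
        "chi2_statistic": r.chi2_statistic,
        "p_raw": r.p_raw,
        "p_bonferroni": r.p_bonferroni,
        "excluded": r.excluded,
        "exclusion_reasons": "; ".join(r.exclusion_reasons),
    }


def _config_dict(config: ScreenConfig) -> dict:
    d = dataclasses.asdict(config)
    d["match"]["features"] = list(d["match"]["features"])
    return d


def top_findings(results, top_k: int) -> list:
    """The smallest-p non-excluded results, at most ``top_k`` of them."""
    kept = [r for r in results if not r.excluded and np.isfinite(r.p_raw)]
    kept.sort(key=lambda r: (r.p_raw, r.drug_class))
    return kept[:top_k]


def write_report(
    results, path: str | os.PathLike, format: str = "json", config: ScreenConfig | None = None
) -> None:
    """Write the full screen table plus the top-k findings section.

    JSON carries the configuration echo, every result (with balance
    diagnostics), and the findings; CSV carries the same flat fields with
    ``#``-prefixed header lines and a second findings section. Output is
    deterministic for a given result list.
    """
    config = config or ScreenConfig()
    if not list(results):
        raise ValidationError("write_report requires a non-empty result list")
    finds = top_findings(results, config.top_k)
    if format == "json":
        payload = {
            "tool": "glyscreen",
            "seed": config.seed,
            "config": _config_dict(config),
            "n_tested": len(results),
            "results": [_flat(r) for r in results],
            "top_findings": [_flat(r) for r in finds],
        }
        for rec, r in zip(payload["results"], results):
            if r.balance is not None:
                rec["balance"] = {
                    "resampling_rate": r.balance.resampling_rate,
                    "verdict": r.balance.verdict,
                    "ks": {k: list(v) for k, v in r.balance.ks.items()},
                }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    elif format == "csv":
        lines = [f"# tool: glyscreen", f"# seed: {config.seed}", f"# n_tested: {len(results)}"]
        lines.append(",".join(_CSV_FIELDS))
        def fmt(v):
            s = repr(v) if isinstance(v, float) else str(v)
            return '"' + s.replace('"', '""') + '"' if ("," in s or '"' in s) else s
        for r in results:
            rec = _flat(r)
            lines.append(",".join(fmt(rec[f]) for f in _CSV_FIELDS))
        lines.append("# top_findings")
        for r in finds:
            rec = _flat(r)
            lines.append(",".join(fmt(rec[f]) for f in _CSV_FIELDS))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")
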