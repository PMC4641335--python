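"""Psychometric validation of the screening instrument against full-length
criterion questionnaires and the PAM-13 activation score.

Implements the validation pipeline used for short screening instruments:

* criterion validity — positive/negative predictive value of the screener's
  barrier flag against the criterion instrument's flag, plus sum-score
  correlations (Pearson when both vectors pass a normality check, otherwise
  Spearman);
* reliability — Cronbach's alpha per construct on complete cases;
* convergent construct validity — univariate ANOVA screen of dichotomised
  barrier flags against PAM-13, followed by a forced-entry multivariate OLS
  regression of PAM-13 on the retained flags.

PPV = TP / (TP + FP): of respondents flagged by the screener, the fraction
confirmed by the criterion instrument.  NPV = TN / (TN + FN): of respondents
cleared by the screener, the fraction confirmed barrier-free.  Respondents
not scorable on either side are excluded from the table and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .instrument import BarrierCategory, InstrumentDefinition
from .scoring import SemasProfile, recode_item

__all__ = [
    "ContingencyTable",
    "CriterionRule",
    "CriterionRuleSet",
    "CriterionResult",
    "StyleResult",
    "RegressionResult",
    "ValidationReport",
    "cronbach_alpha",
    "ppv_npv",
    "correlation",
    "anova_screen",
    "convergent_regression",
    "validation_report",
    "load_criterion_rules",
]


# ---------------------------------------------------------------------------
# reliability


@dataclass(frozen=True)
class AlphaResult:
    value: float | None
    n: int
    k: int
    reason: str = ""


def cronbach_alpha(item_scores) -> AlphaResult:
    """Cronbach's alpha on complete cases.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with sample (n-1) variances.  Rows with any missing value are dropped.

    Parameters
    ----------
    item_scores:
        n x k array-like or DataFrame of item scores (k >= 2).

    Returns
    -------
    AlphaResult with ``value`` None (and a reason) when fewer than 2 complete
    cases remain or the total-score variance is zero.
    """
    m = np.asarray(pd.DataFrame(item_scores), dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("cronbach_alpha requires an n x k matrix with k >= 2")
    complete = m[~np.isnan(m).any(axis=1)]
    n, k = complete.shape
    if n < 2:
        return AlphaResult(None, n, k, reason="fewer than 2 complete cases")
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return AlphaResult(None, n, k, reason="zero total-score variance")
    item_var = complete.var(axis=0, ddof=1).sum()
    return AlphaResult(k / (k - 1) * (1.0 - item_var / total_var), n, k)


# ---------------------------------------------------------------------------
# criterion validity


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return None if d == 0 else self.tp / d

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return None if d == 0 else self.tn / d


def ppv_npv(
    semas_flag: Sequence[bool | None],
    criterion_flag: Sequence[bool | None],
) -> tuple[ContingencyTable, float | None, float | None]:
    """Cross-tabulate screener vs criterion barrier flags and derive PPV/NPV.

    ``None`` on either side marks a not-scorable respondent: excluded from
    the table, counted in ``n_excluded``.  A zero denominator yields PPV or
    NPV of None (undefined), never 0.
    """
    s = list(semas_flag)
    c = list(criterion_flag)
    if len(s) != len(c):
        raise ValueError("flag vectors must be aligned by respondent")
    tp = fp = fn = tn = excl = 0
    for sf, cf in zip(s, c):
        if sf is None or cf is None:
            excl += 1
        elif sf and cf:
            tp += 1
        elif sf and not cf:
            fp += 1
        elif not sf and cf:
            fn += 1
        else:
            tn += 1
    table = ContingencyTable(tp, fp, fn, tn, excl)
    return table, table.ppv, table.npv


def correlation(x, y) -> tuple[float | None, str, float | None]:
    """Correlate two paired sum-score vectors, choosing the method by a
    normality check.

    Each vector is tested with Shapiro-Wilk at alpha = 0.05; if both pass,
    Pearson's r is used, otherwise Spearman's rho (average ranks for ties).
    Incomplete pairs are dropped. Returns (coefficient, method, p).
    """
    df = pd.DataFrame({"x": np.asarray(x, dtype=float), "y": np.asarray(y, dtype=float)}).dropna()
    if len(df) < 3:
        return None, "undefined", None
    xv, yv = df["x"].to_numpy(), df["y"].to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return None, "undefined", None
    normal = all(stats.shapiro(v).pvalue > 0.05 for v in (xv, yv))
    if normal:
        r = stats.pearsonr(xv, yv)
        return float(r.statistic), "pearson", float(r.pvalue)
    r = stats.spearmanr(xv, yv)
    return float(r.statistic), "spearman", float(r.pvalue)


# ---------------------------------------------------------------------------
# criterion rules: map full criterion-instrument responses to a barrier flag


@dataclass(frozen=True)
class CriterionRule:
    """Maps one criterion instrument's responses to barrier present/absent.

    Kinds
    -----
    ``low_sum``     barrier iff item sum <= threshold (e.g. low competence)
    ``high_sum``    barrier iff item sum >= threshold (e.g. symptom scales)
    ``bands``       explicit (lo, hi, barrier) integer bands on the sum
    ``dominance``   coping styles: barrier unless a single favourable style
                    has the strictly highest mean item score
    ``orientation`` locus: barrier iff the external group's mean item score
                    exceeds the internal group's (tie -> internal)
    ``none``        no PPV/NPV for this construct (reported as N.A.)
    """

    construct_id: str
    kind: str
    items: tuple[str, ...] = ()
    threshold: float | None = None
    bands: tuple[tuple[float, float, bool], ...] = ()
    groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    favourable_styles: tuple[str, ...] = ("P",)

    def all_items(self) -> tuple[str, ...]:
        if self.groups:
            return tuple(i for grp in self.groups.values() for i in grp)
        return self.items

    def flag(self, row: Mapping[str, float]) -> bool | None:
        """Barrier flag for one respondent's criterion responses (None if any
        required item is missing)."""
        if self.kind == "none":
            return None
        vals = {i: row.get(i) for i in self.all_items()}
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals.values()):
            return None
        if self.kind in ("low_sum", "high_sum"):
            total = sum(vals[i] for i in self.items)
            if self.threshold is None:
                raise ValueError(f"criterion rule {self.construct_id!r}: threshold required")
            return total <= self.threshold if self.kind == "low_sum" else total >= self.threshold
        if self.kind == "bands":
            total = sum(vals[i] for i in self.items)
            for lo, hi, barrier in self.bands:
                if lo <= total <= hi:
                    return barrier
            raise ValueError(f"criterion rule {self.construct_id!r}: sum {total} outside bands")
        if self.kind == "dominance":
            means = {g: np.mean([vals[i] for i in items]) for g, items in self.groups.items()}
            best = max(means.values())
            dominant = {g for g, v in means.items() if v == best}
            return not (len(dominant) == 1 and dominant <= set(self.favourable_styles))
        if self.kind == "orientation":
            internal = np.mean([vals[i] for i in self.groups["internal"]])
            external = np.mean([vals[i] for i in self.groups["external"]])
            return external > internal
        raise ValueError(f"unknown criterion rule kind {self.kind!r}")

    def sum_score(self, row: Mapping[str, float]) -> float | None:
        """Criterion sum score for correlation (orientation: internal minus
        external mean; dominance rules correlate per style elsewhere)."""
        vals = {i: row.get(i) for i in self.all_items()}
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals.values()):
            return None
        if self.kind == "orientation":
            return float(
                np.mean([vals[i] for i in self.groups["internal"]])
                - np.mean([vals[i] for i in self.groups["external"]])
            )
        return float(sum(vals.values()))


CriterionRuleSet = Mapping[str, CriterionRule]


def load_criterion_rules(doc: Mapping) -> dict[str, CriterionRule]:
    """Build a CriterionRuleSet from a parsed config mapping."""
    rules = {}
    for cid, raw in doc.items():
        rules[cid] = CriterionRule(
            construct_id=cid,
            kind=raw["kind"],
            items=tuple(raw.get("items", ())),
            threshold=raw.get("threshold"),
            bands=tuple((b["lo"], b["hi"], bool(b["barrier"])) for b in raw.get("bands", ())),
            groups={g: tuple(items) for g, items in raw.get("groups", {}).items()},
            favourable_styles=tuple(raw.get("favourable_styles", ("P",))),
        )
    return rules


# ---------------------------------------------------------------------------
# construct validity: ANOVA screen + forced-entry regression


@dataclass(frozen=True)
class ScreenResult:
    construct_id: str
    f_stat: float | None
    p_value: float | None
    retained: bool
    reason: str = ""


def anova_screen(
    barrier_flags: pd.DataFrame,
    pam_scores: pd.Series,
    alpha: float = 0.05,
) -> dict[str, ScreenResult]:
    """One-way ANOVA of PAM-13 between barrier vs no-barrier groups.

    ``barrier_flags``: one boolean/NA column per construct (True = barrier).
    A construct is retained when its two-group F test has p < ``alpha``.
    Constructs with a group of fewer than 2 members are skipped.
    """
    results = {}
    pam = pd.to_numeric(pam_scores, errors="coerce")
    for cid in barrier_flags.columns:
        flags = barrier_flags[cid]
        mask = flags.notna() & pam.notna()
        g1 = pam[mask & (flags == True)]  # noqa: E712 - pandas boolean with NA
        g0 = pam[mask & (flags == False)]  # noqa: E712
        if len(g1) < 2 or len(g0) < 2:
            results[cid] = ScreenResult(cid, None, None, False, reason="group with < 2 members")
            continue
        f, p = stats.f_oneway(g0.to_numpy(), g1.to_numpy())
        results[cid] = ScreenResult(cid, float(f), float(p), bool(p < alpha))
    return results


@dataclass(frozen=True)
class PredictorEffect:
    beta: float
    se_beta: float
    standardized_beta: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    intercept: float
    effects: dict[str, PredictorEffect]
    r_squared: float
    n: int


def convergent_regression(
    barrier_flags: pd.DataFrame,
    pam_scores: pd.Series,
    predictors: Iterable[str] | None = None,
) -> RegressionResult:
    """Forced-entry OLS of PAM-13 on dichotomised barrier-absence indicators.

    Predictors are coded 1 = no barrier, 0 = barrier, so a positive beta is
    the PAM-point advantage of barrier-free respondents.  Listwise complete
    cases.  Raises on a rank-deficient design, naming the collinear columns.
    """
    cols = list(predictors) if predictors is not None else list(barrier_flags.columns)
    if not cols:
        raise ValueError("no predictors retained for regression")
    pam = pd.to_numeric(pam_scores, errors="coerce")
    design = pd.DataFrame(
        {c: (~barrier_flags[c].astype("boolean")).astype("Float64") for c in cols}
    )
    data = design.assign(_pam=pam).dropna()
    if len(data) <= len(cols) + 1:
        raise ValueError("too few complete cases for regression")
    X = data[cols].astype(float)
    if np.linalg.matrix_rank(sm.add_constant(X).to_numpy()) < len(cols) + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; collinear predictors include {worst}")
    y = data["_pam"].astype(float)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    sd_y = y.std(ddof=1)
    effects = {}
    for c in cols:
        sd_x = X[c].std(ddof=1)
        effects[c] = PredictorEffect(
            beta=float(fit.params[c]),
            se_beta=float(fit.bse[c]),
            standardized_beta=float(fit.params[c] * sd_x / sd_y),
            p_value=float(fit.pvalues[c]),
        )
    return RegressionResult(
        intercept=float(fit.params["const"]),
        effects=effects,
        r_squared=float(fit.rsquared),
        n=int(len(data)),
    )


# ---------------------------------------------------------------------------
# full validation report


@dataclass(frozen=True)
class StyleResult:
    alpha: float | None
    corr: float | None
    corr_method: str
    p_value: float | None
    n: int


@dataclass(frozen=True)
class CriterionResult:
    construct_id: str
    n: int
    ppv: float | None
    npv: float | None
    table: ContingencyTable | None
    alpha: float | None
    corr: float | None
    corr_method: str
    p_value: float | None
    styles: dict[str, StyleResult] = field(default_factory=dict)
    notes: str = ""


@dataclass(frozen=True)
class ValidationReport:
    rows: tuple[CriterionResult, ...]
    screen: dict[str, ScreenResult]
    regression: RegressionResult | None
    n_respondents: int
    issues: tuple[str, ...] = ()


def _semas_item_matrix(
    profiles: Sequence[SemasProfile],
    instrument: InstrumentDefinition,
    item_ids: Sequence[str],
    records_by_id: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    items = instrument.items
    rows = {}
    for p in profiles:
        raw = records_by_id.get(p.respondent_id, {})
        rows[p.respondent_id] = {
            iid: recode_item(items[iid], raw.get(iid)) for iid in item_ids
        }
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float)


def _unit_sum(profile: SemasProfile, unit: str) -> float | None:
    sc = profile.scores.get(unit)
    return None if sc is None or sc.sum_score is None else float(sc.sum_score)


def _unit_flag(profile: SemasProfile, unit: str) -> bool | None:
    sc = profile.scores.get(unit)
    if sc is None or sc.category is BarrierCategory.NOT_SCORABLE:
        return None
    return sc.category.is_barrier


def barrier_flag_frame(
    profiles: Sequence[SemasProfile], instrument: InstrumentDefinition
) -> pd.DataFrame:
    """Respondent x barrier-unit frame of dichotomised flags (pandas NA for
    not scorable)."""
    units = instrument.barrier_units()
    data = {
        u: [_unit_flag(p, u) for p in profiles]
        for u in units
    }
    return pd.DataFrame(data, index=[p.respondent_id for p in profiles], dtype="boolean")


# units with no PPV/NPV in the published validation (no criterion rule)
_NA_DEFAULT = ("social_support", "burden")


def validation_report(
    profiles: Sequence[SemasProfile],
    semas_records: Mapping[str, Mapping[str, float]],
    criterion_responses: pd.DataFrame,
    pam_scores: pd.Series,
    rules: CriterionRuleSet,
    instrument: InstrumentDefinition,
    screen_alpha: float = 0.05,
) -> ValidationReport:
    """Run the full validation pipeline on an aligned cohort.

    Parameters
    ----------
    profiles:
        Scored SeMaS profiles (from :func:`semas.scoring.score_cohort`).
    semas_records:
        respondent_id -> raw SeMaS responses (for per-item alpha matrices).
    criterion_responses:
        DataFrame indexed by respondent_id, one column per criterion item
        (already on the criterion instrument's score metric).
    pam_scores:
        Series indexed by respondent_id, PAM-13 on the 0-100 scale.
    rules:
        CriterionRuleSet mapping barrier units to criterion flag rules.
    """
    issues: list[str] = []
    ids = [p.respondent_id for p in profiles]
    crit = criterion_responses.reindex(ids)
    pam = pd.to_numeric(pam_scores, errors="coerce").reindex(ids)

    rows: list[CriterionResult] = []
    units = instrument.barrier_units()
    for unit in units:
        rule = rules.get(unit)
        table = ppv = npv = None
        if rule is not None and rule.kind != "none":
            semas_flags = [_unit_flag(p, unit) for p in profiles]
            crit_flags = [rule.flag(crit.loc[rid].to_dict()) for rid in ids]
            table, ppv, npv = ppv_npv(semas_flags, crit_flags)
        elif rule is None and unit not in _NA_DEFAULT:
            issues.append(f"{unit}: no criterion rule supplied; PPV/NPV not computed")

        styles: dict[str, StyleResult] = {}
        alpha_val: float | None = None
        corr_val = corr_p = None
        corr_method = "n.a."
        comp = instrument.composites.get(unit)
        if comp is not None and comp.kind.value == "style_dominance":
            # per-style alpha and correlation against per-style criterion sums
            for style, member in comp.style_labels.items():
                member_items = [it.item_id for it in instrument.constructs[member].items]
                mat = _semas_item_matrix(profiles, instrument, member_items, semas_records)
                a = cronbach_alpha(mat)
                semas_sums = [_unit_sum(p, member) for p in profiles]
                crit_items = rule.groups.get(style, ()) if rule else ()
                if crit_items:
                    crit_sums = crit[list(crit_items)].sum(axis=1, min_count=len(crit_items))
                    c, method, p_val = correlation(semas_sums, crit_sums)
                else:
                    c, method, p_val = None, "n.a.", None
                n_pairs = int(
                    pd.DataFrame({"a": pd.Series(semas_sums, dtype=float)}).dropna().shape[0]
                )
                styles[style] = StyleResult(a.value, c, method, p_val, n_pairs)
        else:
            if unit in instrument.composites:  # locus dichotomy
                comp_rule = instrument.composites[unit]
                item_ids = [
                    it.item_id
                    for m in comp_rule.members
                    for it in instrument.constructs[m].items
                ]
            else:
                item_ids = [it.item_id for it in instrument.constructs[unit].items]
            if len(item_ids) >= 2:
                mat = _semas_item_matrix(profiles, instrument, item_ids, semas_records)
                alpha_val = cronbach_alpha(mat).value
            semas_sums = [_unit_sum(p, unit) for p in profiles]
            # correlations are computed whenever criterion items exist, even
            # for constructs with no PPV/NPV rule (kind 'none')
            if rule is not None and rule.all_items():
                crit_sums = [rule.sum_score(crit.loc[rid].to_dict()) for rid in ids]
                corr_val, corr_method, corr_p = correlation(semas_sums, crit_sums)

        n_scorable = sum(_unit_flag(p, unit) is not None for p in profiles)
        rows.append(
            CriterionResult(
                construct_id=unit,
                n=table.n if table is not None else n_scorable,
                ppv=ppv,
                npv=npv,
                table=table,
                alpha=alpha_val,
                corr=corr_val,
                corr_method=corr_method,
                p_value=corr_p,
                styles=styles,
                notes="N.A." if (rule is None or rule.kind == "none") else "",
            )
        )

    flags = barrier_flag_frame(profiles, instrument)
    screen = anova_screen(flags, pam, alpha=screen_alpha)
    retained = [c for c, r in screen.items() if r.retained]
    regression = None
    if retained:
        try:
            regression = convergent_regression(flags, pam, predictors=retained)
        except ValueError as exc:
            issues.append(f"regression failed: {exc}")
    else:
        issues.append("no construct passed the ANOVA screen; regression skipped")

    return ValidationReport(
        rows=tuple(rows),
        screen=screen,
        regression=regression,
        n_respondents=len(profiles),
        issues=tuple(issues),
    )
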