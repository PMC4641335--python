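"""Synthetic respondent cohorts for exercising the scoring engine and the
validation pipeline without patient data.

The generator emulates the statistical structure a questionnaire validation
study assumes:

* correlated construct-level latent traits (multivariate normal);
* graded-threshold (ordinal probit) item responses — each Likert response is
  the category of ``loading * trait + noise`` against ordered cut-points;
* a criterion channel: full-length criterion instruments driven by the same
  traits with independent noise;
* a PAM-13 channel: activation score built from the true barrier-absence
  flags plus noise, clamped to 0-100;
* independent per-item missingness.

The ``truth`` channel (latent traits and noiseless barrier flags) is written
for tests only; scoring and psychometrics never read it.  Truth flags are
computed by the generator's own straight-line arithmetic (thresholds applied
to the noiseless propensity, summed, banded), independent of the scoring
engine, so the two routes cross-check each other.

A single integer seed drives all channels through independent substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import (
    BarrierCategory,
    ConstructRole,
    InstrumentDefinition,
    RuleKind,
    default_instrument,
)
from .psychometrics import CriterionRule, CriterionRuleSet
from .scoring import ResponseRecord

__all__ = [
    "TRAITS",
    "CohortConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "calibrate_prevalence",
    "criterion_rules_for",
    "default_cohort_config",
]

# One latent trait per scored elementary construct family.  Locus uses a
# single "internality" trait: the internal item loads positively, the
# external item negatively.
TRAITS = (
    "self_efficacy",
    "coping_P",
    "coping_E",
    "coping_D",
    "depression",
    "anxiety",
    "locus",
    "social_support",
    "burden",
)

_CONSTRUCT_TRAIT = {
    "self_efficacy": ("self_efficacy", +1),
    "coping_P": ("coping_P", +1),
    "coping_E": ("coping_E", +1),
    "coping_D": ("coping_D", +1),
    "depression": ("depression", +1),
    "anxiety": ("anxiety", +1),
    "locus_internal": ("locus", +1),
    "locus_external": ("locus", -1),
    "social_support": ("social_support", +1),
    "burden": ("burden", +1),
}


def default_trait_corr() -> np.ndarray:
    """Moderately correlated trait structure: anxiety/depression cluster,
    self-efficacy aligned with activation-favourable traits."""
    idx = {t: i for i, t in enumerate(TRAITS)}
    corr = np.eye(len(TRAITS))

    def set_(a: str, b: str, rho: float) -> None:
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho

    set_("depression", "anxiety", 0.55)
    set_("self_efficacy", "depression", -0.35)
    set_("self_efficacy", "anxiety", -0.25)
    set_("self_efficacy", "locus", 0.30)
    set_("self_efficacy", "social_support", 0.20)
    set_("self_efficacy", "burden", -0.25)
    set_("depression", "burden", 0.30)
    set_("anxiety", "burden", 0.25)
    set_("depression", "social_support", -0.20)
    set_("coping_P", "self_efficacy", 0.25)
    set_("coping_E", "anxiety", 0.20)
    set_("coping_D", "coping_E", 0.25)
    set_("coping_P", "coping_D", 0.15)
    return corr


# Threshold offsets (probit scale) per elementary construct, calibrated with
# calibrate_prevalence() against the default barrier-prevalence scenario
# (anxiety rare, coping and external locus common; see docs/methods.md).
DEFAULT_OFFSETS: dict[str, float] = {
    "self_efficacy": -0.984,
    "coping_P": -0.422,
    "coping_E": 0.0,
    "coping_D": 0.0,
    "depression": 1.734,
    "anxiety": 2.109,
    "locus_internal": 0.656,
    "locus_external": 0.0,
    "social_support": -1.031,
    "guidance": 0.0,
}

# Default per-construct barrier prevalences the offsets aim at (the spirit of
# the published cohort's distribution: coping/locus barriers common, anxiety
# rare).
DEFAULT_PREVALENCE = {
    "self_efficacy": 0.18,
    "coping": 0.65,
    "depression": 0.12,
    "anxiety": 0.05,
    "locus": 0.55,
    "social_support": 0.10,
    "burden": 0.30,
}

# Per-construct independent item missingness (echoes the reported pattern:
# burden and social support most often incomplete, self-efficacy rarely).
DEFAULT_MISSING: dict[str, float] = {
    "self_efficacy": 0.01,
    "coping_P": 0.04,
    "coping_E": 0.04,
    "coping_D": 0.04,
    "depression": 0.01,
    "anxiety": 0.015,
    "locus_internal": 0.06,
    "locus_external": 0.06,
    "social_support": 0.08,
    "burden": 0.15,
    "computer_skills": 0.02,
    "group_functioning": 0.02,
    "self_monitoring_willingness": 0.02,
}

# PAM-13 channel: activation points contributed by the absence of each
# barrier (the published regression estimates serve as the default effect
# sizes; coping did not pass the screen there and defaults to zero).
DEFAULT_PAM_COEFFICIENTS: dict[str, float] = {
    "self_efficacy": 16.43,
    "social_support": 6.64,
    "locus": 2.99,
    "anxiety": 0.84,
    "depression": 0.04,
    "burden": 3.51,
    "coping": 0.0,
}

# Criterion-channel design: full-length originals feeding each barrier unit.
# (item counts per group; codes per item; rule kind)
_FULL_CRITERION = {
    "self_efficacy": {"groups": {"": 2}, "codes": 4, "kind": "low_sum"},
    "coping": {"groups": {"P": 5, "E": 4, "D": 5}, "codes": 4, "kind": "dominance"},
    "depression": {"groups": {"": 6}, "codes": 5, "kind": "high_sum"},
    "anxiety": {"groups": {"": 12}, "codes": 5, "kind": "high_sum"},
    "locus": {"groups": {"internal": 6, "external": 12}, "codes": 6, "kind": "orientation"},
    "social_support": {"groups": {"": 5}, "codes": 4, "kind": "none"},
    "burden": {"groups": {"": 1}, "codes": 0, "kind": "none"},  # VAS
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic validation cohort.

    Defaults describe the package's standard scenario: 204 respondents,
    moderately correlated traits, item discrimination 1.2, unit-variance
    response noise on both channels, barrier prevalences echoing the
    published cohort's spread, and realistic item missingness.
    """

    n: int = 204
    seed: int = 0
    trait_corr: np.ndarray | None = None
    loading: float = 1.2
    semas_noise_sd: float = 1.0
    criterion_noise_sd: float = 1.0
    threshold_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OFFSETS)
    )
    burden_slope: float = 2.2
    burden_spread: float = 1.0
    pam_intercept: float = 34.5
    pam_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAM_COEFFICIENTS)
    )
    pam_noise_sd: float = 12.0
    missing_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSING))
    # explicit per-item ordered cut-points on the propensity scale; overrides
    # the equiprobable default ladder for those items
    item_cutpoints: Mapping[str, Sequence[float]] = field(default_factory=dict)
    criterion_design: str = "full"  # "full" or "mirror"
    prevalence_targets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )

    def corr_matrix(self) -> np.ndarray:
        corr = self.trait_corr if self.trait_corr is not None else default_trait_corr()
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (len(TRAITS), len(TRAITS)):
            raise ValueError(f"trait_corr must be {len(TRAITS)}x{len(TRAITS)}")
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError("trait_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("trait_corr is not positive semi-definite")
        return corr

    def offset(self, construct_id: str) -> float:
        return float(self.threshold_offsets.get(construct_id, 0.0))

    def cutpoints_for(self, item_id: str, n_codes: int, construct_id: str) -> np.ndarray:
        custom = self.item_cutpoints.get(item_id)
        if custom is not None:
            cuts = np.asarray(custom, dtype=float)
            if len(cuts) != n_codes - 1 or np.any(np.diff(cuts) <= 0):
                raise ValueError(
                    f"item {item_id!r}: needs {n_codes - 1} strictly increasing cut-points"
                )
            return cuts
        return _cutpoints(n_codes, self.offset(construct_id), self.loading)

    def missing(self, construct_id: str) -> float:
        rate = float(self.missing_rates.get(construct_id, 0.0))
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"missing rate for {construct_id!r} must be in [0, 1)")
        return rate


@dataclass
class SyntheticCohort:
    """All generated channels, aligned by respondent_id."""

    semas_records: list[ResponseRecord]
    criterion_responses: pd.DataFrame
    pam_scores: pd.Series
    truth: pd.DataFrame  # traits + true per-unit barrier flags + categories
    config: CohortConfig


def _cutpoints(n_codes: int, offset: float, loading: float) -> np.ndarray:
    """Ordered thresholds on the propensity scale.

    Base cut-points put the categories at equal probability for a standard
    respondent; the construct offset shifts the whole ladder.  Cut-points are
    scaled by the propensity's standard deviation so offsets stay on a probit
    scale regardless of loading.
    """
    base = stats.norm.ppf(np.arange(1, n_codes) / n_codes)
    scale = np.sqrt(loading**2 + 1.0)
    return scale * (base + offset)


def _ordinal(z: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Category index 0..m-1 of each propensity against ordered cuts."""
    return np.searchsorted(cuts, z, side="left")


def _truth_categories(
    instrument: InstrumentDefinition,
    noiseless_scores: Mapping[str, np.ndarray],
    noiseless_vas: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Generator-side banding of noiseless sum scores (independent of the
    scoring engine): returns per-unit barrier flags."""
    flags: dict[str, np.ndarray] = {}
    sums: dict[str, np.ndarray] = {}
    for cid, con in instrument.constructs.items():
        if con.role is ConstructRole.GUIDANCE:
            continue
        if con.is_vas:
            sums[cid] = noiseless_vas[cid]
        else:
            sums[cid] = np.sum([noiseless_scores[it.item_id] for it in con.items], axis=0)
        rule = con.category_rule
        if rule.rule_kind in (RuleKind.BANDED, RuleKind.U_SHAPED, RuleKind.EXTERNAL_TABLE):
            vals = np.floor(sums[cid] + 0.5).astype(int) if con.is_vas else sums[cid].astype(int)
            flag = np.zeros(len(vals), dtype=bool)
            for lo, hi, cat in rule.bands:
                if cat in (BarrierCategory.MINOR, BarrierCategory.MAJOR):
                    flag |= (vals >= lo) & (vals <= hi)
            flags[cid] = flag
    for comp_id, comp in instrument.composites.items():
        if comp.kind is RuleKind.STYLE_DOMINANCE:
            style_sums = np.vstack([sums[m] for m in comp.members])
            best = style_sums.max(axis=0)
            is_best = style_sums == best
            n_best = is_best.sum(axis=0)
            favourable = np.array(
                [comp.style_category.get(s, BarrierCategory.MINOR) is BarrierCategory.NONE
                 for s in comp.style_labels]
            )
            single_fav = (n_best == 1) & (is_best & favourable[:, None]).any(axis=0)
            multi_barrier = comp.multiple_styles_category is not BarrierCategory.NONE
            flags[comp_id] = np.where(n_best > 1, multi_barrier, ~single_fav)
        else:
            internal, external = sums[comp.internal], sums[comp.external]
            is_internal = (
                internal > external
                if comp.tie == "external"
                else internal >= external
            )
            orient_barrier = {
                k: v in (BarrierCategory.MINOR, BarrierCategory.MAJOR)
                for k, v in comp.orientation_category.items()
            }
            flags[comp_id] = np.where(
                is_internal,
                orient_barrier.get("internal", False),
                orient_barrier.get("external", True),
            )
    return flags


def simulate_cohort(
    config: CohortConfig,
    instrument: InstrumentDefinition | None = None,
) -> SyntheticCohort:
    """Generate a fully reproducible synthetic cohort.

    All randomness derives from ``config.seed`` through named substreams, so
    identical configs yield byte-identical cohorts.
    """
    instrument = instrument or default_instrument()
    corr = config.corr_matrix()
    n = config.n
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("traits", "semas", "vas", "criterion", "missing_semas",
             "missing_criterion", "pam", "guidance"),
            ss.spawn(8),
        )
    }

    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(TRAITS)))
    traits = streams["traits"].standard_normal((n, len(TRAITS))) @ chol.T
    trait_of = {t: traits[:, i] for i, t in enumerate(TRAITS)}

    lam = config.loading
    responses: dict[str, np.ndarray] = {}  # item_id -> raw codes / VAS values
    noiseless_scores: dict[str, np.ndarray] = {}
    noiseless_vas: dict[str, np.ndarray] = {}

    for cid, con in instrument.constructs.items():
        if con.role is ConstructRole.GUIDANCE:
            # Guidance items steer intervention choice, not barriers: codes
            # drawn uniformly, independent of the traits.
            for it in con.items:
                codes = np.array(it.scale.codes)  # type: ignore[union-attr]
                responses[it.item_id] = streams["guidance"].choice(codes, size=n)
            continue
        trait_name, sign = _CONSTRUCT_TRAIT[cid]
        t = sign * trait_of[trait_name]
        if con.is_vas:
            item = con.items[0]
            signal = 5.0 + config.burden_spread * config.burden_slope * t
            noisy = signal + config.semas_noise_sd * streams["vas"].standard_normal(n)
            responses[item.item_id] = np.round(np.clip(noisy, 0.0, 10.0), 1)
            noiseless_vas[cid] = np.round(np.clip(signal, 0.0, 10.0), 1)
            continue
        for it in con.items:
            cuts = config.cutpoints_for(it.item_id, len(it.scale.levels), cid)  # type: ignore[union-attr]
            z = lam * t + config.semas_noise_sd * streams["semas"].standard_normal(n)
            idx = _ordinal(z, cuts)
            codes = np.array(it.scale.codes)  # type: ignore[union-attr]
            scores = np.array([it.scale.score_map[c] for c in codes])  # type: ignore[union-attr]
            responses[it.item_id] = codes[idx]
            idx0 = _ordinal(lam * t, cuts)
            s0 = scores[idx0]
            if it.reverse:
                s0 = it.max_score - s0
            noiseless_scores[it.item_id] = s0

    truth_flags = _truth_categories(instrument, noiseless_scores, noiseless_vas)

    # --- criterion channel -------------------------------------------------
    crit_cols: dict[str, np.ndarray] = {}
    crit_missing_rate: dict[str, float] = {}
    if config.criterion_design == "mirror":
        # identical item structure: criterion columns hold the recoded score
        # of a fresh draw from the same thresholds (same trait, criterion
        # noise); with zero noise both channels coincide exactly
        for cid, con in instrument.constructs.items():
            if con.role is ConstructRole.GUIDANCE:
                continue
            trait_name, sign = _CONSTRUCT_TRAIT[cid]
            t = sign * trait_of[trait_name]
            if con.is_vas:
                signal = 5.0 + config.burden_spread * config.burden_slope * t
                noisy = signal + config.criterion_noise_sd * streams["criterion"].standard_normal(n)
                crit_cols[f"crit_{con.items[0].item_id}"] = np.round(np.clip(noisy, 0, 10), 1)
                crit_missing_rate[f"crit_{con.items[0].item_id}"] = config.missing(cid)
                continue
            for it in con.items:
                cuts = config.cutpoints_for(it.item_id, len(it.scale.levels), cid)  # type: ignore[union-attr]
                z = lam * t + config.criterion_noise_sd * streams["criterion"].standard_normal(n)
                idx = _ordinal(z, cuts)
                codes = np.array(it.scale.codes)  # type: ignore[union-attr]
                score_arr = np.array([it.scale.score_map[c] for c in codes])  # type: ignore[union-attr]
                s = score_arr[idx]
                if it.reverse:
                    s = it.max_score - s
                crit_cols[f"crit_{it.item_id}"] = s
                crit_missing_rate[f"crit_{it.item_id}"] = config.missing(cid)
    else:
        for unit, design in _FULL_CRITERION.items():
            if design["codes"] == 0:  # VAS criterion (perceived health status)
                t = trait_of["burden"]
                signal = 5.0 + config.burden_spread * config.burden_slope * t
                noisy = signal + config.criterion_noise_sd * streams["criterion"].standard_normal(n)
                crit_cols["crit_burden_vas"] = np.round(np.clip(noisy, 0, 10), 1)
                crit_missing_rate["crit_burden_vas"] = config.missing("burden")
                continue
            for group, k in design["groups"].items():
                if unit == "coping":
                    trait_name, sign, offset_key = f"coping_{group}", +1, f"coping_{group}"
                elif unit == "locus":
                    trait_name = "locus"
                    sign = +1 if group == "internal" else -1
                    offset_key = f"locus_{group}"
                else:
                    trait_name, sign, offset_key = unit, +1, unit
                t = sign * trait_of[trait_name]
                cuts = _cutpoints(design["codes"], config.offset(offset_key), lam)
                for j in range(k):
                    z = lam * t + config.criterion_noise_sd * streams["criterion"].standard_normal(n)
                    col = f"crit_{unit}{('_' + group) if group else ''}_{j + 1}"
                    crit_cols[col] = _ordinal(z, cuts)  # scores 0..m-1
                    crit_missing_rate[col] = config.missing(offset_key)

    criterion = pd.DataFrame(crit_cols, index=[f"r{i + 1:04d}" for i in range(n)], dtype=float)
    for col in criterion.columns:
        rate = crit_missing_rate.get(col, 0.0)
        if rate > 0:
            mask = streams["missing_criterion"].random(n) < rate
            criterion.loc[mask, col] = np.nan

    # --- missingness on the SeMaS channel ----------------------------------
    missing_mask: dict[str, np.ndarray] = {}
    for cid, con in instrument.constructs.items():
        rate = config.missing(cid)
        for it in con.items:
            missing_mask[it.item_id] = (
                streams["missing_semas"].random(n) < rate
                if rate > 0
                else np.zeros(n, dtype=bool)
            )

    ids = [f"r{i + 1:04d}" for i in range(n)]
    records = []
    for i, rid in enumerate(ids):
        resp: dict[str, float | int | None] = {}
        for item_id, values in responses.items():
            if missing_mask[item_id][i]:
                resp[item_id] = None
            else:
                v = values[i]
                resp[item_id] = float(v) if isinstance(v, (float, np.floating)) else int(v)
        records.append(ResponseRecord(respondent_id=rid, responses=resp))

    # --- PAM channel --------------------------------------------------------
    pam = np.full(n, config.pam_intercept, dtype=float)
    for unit, coeff in config.pam_coefficients.items():
        if unit in truth_flags:
            pam += coeff * (~truth_flags[unit]).astype(float)
    pam += config.pam_noise_sd * streams["pam"].standard_normal(n)
    pam = np.clip(pam, 0.0, 100.0)

    truth = pd.DataFrame(
        {f"trait_{t}": traits[:, i] for i, t in enumerate(TRAITS)}, index=ids
    )
    for unit, flag in truth_flags.items():
        truth[f"barrier_{unit}"] = flag

    return SyntheticCohort(
        semas_records=records,
        criterion_responses=criterion,
        pam_scores=pd.Series(pam, index=ids, name="pam"),
        truth=truth,
        config=config,
    )


def criterion_rules_for(
    config: CohortConfig, instrument: InstrumentDefinition | None = None
) -> dict[str, CriterionRule]:
    """Example criterion rules matching the generator's criterion design.

    These mirror the screener's own banding style on the full-length
    instruments and are illustrative: a real validation run must supply the
    criterion instruments' published cut-offs.
    """
    instrument = instrument or default_instrument()
    rules: dict[str, CriterionRule] = {}
    if config.criterion_design == "mirror":
        for unit in instrument.barrier_units():
            comp = instrument.composites.get(unit)
            if comp is not None and comp.kind is RuleKind.STYLE_DOMINANCE:
                groups = {
                    style: tuple(
                        f"crit_{it.item_id}"
                        for it in instrument.constructs[member].items
                    )
                    for style, member in comp.style_labels.items()
                }
                fav = tuple(
                    s for s, c in comp.style_category.items() if c is BarrierCategory.NONE
                )
                rules[unit] = CriterionRule(unit, "dominance", groups=groups,
                                            favourable_styles=fav or ("P",))
            elif comp is not None:
                rules[unit] = CriterionRule(
                    unit,
                    "orientation",
                    groups={
                        "internal": tuple(
                            f"crit_{it.item_id}"
                            for it in instrument.constructs[comp.internal].items
                        ),
                        "external": tuple(
                            f"crit_{it.item_id}"
                            for it in instrument.constructs[comp.external].items
                        ),
                    },
                )
            else:
                con = instrument.constructs[unit]
                items = tuple(f"crit_{it.item_id}" for it in con.items)
                if con.is_vas:
                    # half-up rounding on the 1-decimal VAS grid: value v falls
                    # in integer band [lo, hi] iff lo - 0.5 <= v <= hi + 0.4
                    bands = tuple(
                        (max(0.0, lo - 0.5), hi + 0.4, cat.is_barrier)
                        for lo, hi, cat in con.category_rule.bands
                    )
                    rules[unit] = CriterionRule(unit, "bands", items=items, bands=bands)
                else:
                    bands = tuple(
                        (float(lo), float(hi), cat.is_barrier)
                        for lo, hi, cat in con.category_rule.bands
                    )
                    rules[unit] = CriterionRule(unit, "bands", items=items, bands=bands)
        return rules

    for unit, design in _FULL_CRITERION.items():
        if design["kind"] == "none":
            if unit == "burden":
                rules[unit] = CriterionRule(unit, "none", items=("crit_burden_vas",))
            else:
                k = design["groups"][""]
                rules[unit] = CriterionRule(
                    unit, "none", items=tuple(f"crit_{unit}_{j + 1}" for j in range(k))
                )
            continue
        if design["kind"] == "dominance":
            groups = {
                g: tuple(f"crit_{unit}_{g}_{j + 1}" for j in range(k))
                for g, k in design["groups"].items()
            }
            rules[unit] = CriterionRule(unit, "dominance", groups=groups)
        elif design["kind"] == "orientation":
            groups = {
                g: tuple(f"crit_{unit}_{g}_{j + 1}" for j in range(k))
                for g, k in design["groups"].items()
            }
            rules[unit] = CriterionRule(unit, "orientation", groups=groups)
        else:
            k = design["groups"][""]
            items = tuple(f"crit_{unit}_{j + 1}" for j in range(k))
            max_sum = k * (design["codes"] - 1)
            if design["kind"] == "low_sum":
                rules[unit] = CriterionRule(unit, "low_sum", items=items,
                                            threshold=max_sum // 2)
            else:
                # symptom scales: barrier in the top quarter of the range
                rules[unit] = CriterionRule(unit, "high_sum", items=items,
                                            threshold=int(np.ceil(0.25 * max_sum)))
    return rules


# units whose prevalence is tuned through which offset key (or spread)
_CALIBRATION_KNOB = {
    "self_efficacy": ("offset", "self_efficacy"),
    "coping": ("offset", "coping_P"),
    "depression": ("offset", "depression"),
    "anxiety": ("offset", "anxiety"),
    "locus": ("offset", "locus_internal"),
    "social_support": ("offset", "social_support"),
    "burden": ("spread", "burden"),
}


def _observed_prevalence(config: CohortConfig, instrument: InstrumentDefinition,
                         unit: str, n: int, seed: int) -> float:
    """Barrier prevalence of one unit in a simulated cohort (no missingness),
    measured on the noisy channel (vectorised generator-side banding)."""
    probe = replace(config, n=n, seed=seed, missing_rates={})
    cohort = simulate_cohort(probe, instrument)
    recs = cohort.semas_records
    scores: dict[str, np.ndarray] = {}
    vas: dict[str, np.ndarray] = {}
    for cid, con in instrument.constructs.items():
        if con.role is ConstructRole.GUIDANCE:
            continue
        if con.is_vas:
            vas[cid] = np.array(
                [r.responses[con.items[0].item_id] for r in recs], dtype=float
            )
            continue
        for it in con.items:
            codes = np.array([r.responses[it.item_id] for r in recs], dtype=int)
            smap = it.scale.score_map  # type: ignore[union-attr]
            lut = np.zeros(max(smap) + 1, dtype=int)
            for c, s in smap.items():
                lut[c] = s
            s = lut[codes]
            if it.reverse:
                s = it.max_score - s
            scores[it.item_id] = s
    flags = _truth_categories(instrument, scores, vas)
    return float(np.mean(flags[unit]))


def calibrate_prevalence(
    config: CohortConfig,
    prevalence_targets: Mapping[str, float],
    instrument: InstrumentDefinition | None = None,
    n: int = 10000,
    tol: float = 0.01,
    max_iter: int = 18,
    seed: int = 12345,
) -> CohortConfig:
    """Shift per-construct thresholds so simulated barrier prevalences match
    the targets.

    Bisection on a shared threshold offset per unit (for the u-shaped burden
    construct, on its signal-spread multiplier) against the prevalence
    observed in an n=10000 simulated cohort.  Raises if a target cannot be
    bracketed within the search range.
    """
    instrument = instrument or default_instrument()
    offsets = dict(config.threshold_offsets)
    spread = config.burden_spread
    for unit, target in prevalence_targets.items():
        if not 0.0 < target < 1.0:
            raise ValueError(f"prevalence target for {unit!r} must be in (0, 1)")
        knob_kind, knob_key = _CALIBRATION_KNOB[unit]
        if knob_kind == "offset":
            lo, hi = -3.0, 3.0
        else:
            lo, hi = 0.05, 5.0

        def prev_at(x: float) -> float:
            if knob_kind == "offset":
                probe = replace(config, threshold_offsets={**offsets, knob_key: x},
                                burden_spread=spread)
            else:
                probe = replace(config, threshold_offsets=dict(offsets), burden_spread=x)
            return _observed_prevalence(probe, instrument, unit, n, seed)

        p_lo, p_hi = prev_at(lo), prev_at(hi)
        increasing = p_hi >= p_lo
        if not (min(p_lo, p_hi) - tol <= target <= max(p_lo, p_hi) + tol):
            raise ValueError(
                f"prevalence target {target} for {unit!r} unattainable "
                f"(range [{min(p_lo, p_hi):.3f}, {max(p_lo, p_hi):.3f}])"
            )
        x_best, err_best = lo, abs(p_lo - target)
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            p_mid = prev_at(mid)
            if abs(p_mid - target) < err_best:
                x_best, err_best = mid, abs(p_mid - target)
            if err_best <= tol:
                break
            if (p_mid < target) == increasing:
                lo = mid
            else:
                hi = mid
        if knob_kind == "offset":
            offsets[knob_key] = x_best
        else:
            spread = x_best
    return replace(config, threshold_offsets=offsets, burden_spread=spread)


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """The package's standard 204-respondent scenario."""
    return replace(CohortConfig(seed=seed), **overrides)
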