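"""Turn raw item responses into construct scores, barrier categories and
per-respondent SeMaS profiles.

Scoring follows the published rules: per-item Likert recoding (with the
coping 'often' collapse), construct sum scores, case exclusion on missing
items except for social support (missing = 'not applicable' = 0), banded
barrier categorisation, coping-style dominance and the internal/external
locus dichotomy.  VAS burden values are rounded half-up before banding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .instrument import (
    BarrierCategory,
    CompositeRule,
    ConstructRole,
    ConstructSpec,
    InstrumentDefinition,
    ItemSpec,
    MissingPolicy,
    RuleKind,
    attainable_score_range,
)

__all__ = [
    "MISSING",
    "ResponseRecord",
    "ConstructScore",
    "SemasProfile",
    "ScoringError",
    "recode_item",
    "score_construct",
    "categorize",
    "resolve_coping",
    "resolve_locus",
    "build_profile",
    "score_cohort",
]

MISSING = None  # canonical in-memory representation of a missing response


class ScoringError(ValueError):
    """Raised in strict mode for illegal raw codes or malformed records."""


@dataclass
class ResponseRecord:
    """One respondent's raw responses: item_id -> code, VAS value, or None."""

    respondent_id: str
    responses: dict[str, float | int | None] = field(default_factory=dict)

    def get(self, item_id: str):
        return self.responses.get(item_id, MISSING)


@dataclass(frozen=True)
class ConstructScore:
    """Sum score + barrier category for one construct (or composite)."""

    construct_id: str
    sum_score: float | int | None
    category: BarrierCategory
    n_missing: int = 0

    @property
    def scorable(self) -> bool:
        return self.sum_score is not None


@dataclass
class SemasProfile:
    """Per-respondent scoring result.

    ``scores`` holds one entry per construct plus one per composite ('coping',
    'locus').  ``barrier_count`` counts barrier units (standalone barrier
    constructs and composites, never guidance items) whose category is minor
    or major; not-scorable units are excluded from the count and flagged.
    """

    respondent_id: str
    scores: dict[str, ConstructScore]
    coping_styles: frozenset[str] | None
    locus_orientation: str | None
    guidance_flags: dict[str, int | None]
    barrier_count: int
    not_scorable: tuple[str, ...] = ()
    issues: tuple[str, ...] = ()


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def recode_item(
    item: ItemSpec,
    raw: float | int | None,
    *,
    strict: bool = False,
    issues: list[str] | None = None,
) -> int | float | None:
    """Recode one raw response to its item score.

    Missing propagates.  Likert codes map through the item's scale (reverse
    items as ``max_score - score``); VAS values pass through after range
    checking.  Illegal values are treated as missing in lenient mode (logged
    to ``issues``) and raise :class:`ScoringError` in strict mode.
    """
    if raw is None:
        return MISSING
    if item.is_vas:
        value = float(raw)
        if not 0.0 <= value <= 10.0:
            msg = f"item {item.item_id!r}: VAS value {value} outside [0, 10]"
            if strict:
                raise ScoringError(msg)
            if issues is not None:
                issues.append(msg)
            return MISSING
        return value
    code = int(raw)
    score_map = item.scale.score_map  # type: ignore[union-attr]
    if code not in score_map:
        msg = f"item {item.item_id!r}: code {raw!r} not on scale {item.scale.name!r}"  # type: ignore[union-attr]
        if strict:
            raise ScoringError(msg)
        if issues is not None:
            issues.append(msg)
        return MISSING
    score = score_map[code]
    if item.reverse:
        score = item.max_score - score
    return score


def categorize(construct: ConstructSpec, sum_score: float | int) -> BarrierCategory:
    """Banded category lookup for a present sum score.

    VAS sums are rounded half-up to integers first (the bands are integer
    intervals).  Only applies to banded/u-shaped/external-table rules;
    composite members are categorised via :func:`resolve_coping` /
    :func:`resolve_locus`.
    """
    value = _round_half_up(sum_score) if construct.is_vas else int(sum_score)
    return construct.category_rule.lookup(value)


def score_construct(
    construct: ConstructSpec,
    record: ResponseRecord,
    *,
    strict: bool = False,
    issues: list[str] | None = None,
) -> ConstructScore:
    """Sum a construct's recoded item scores and apply its missing policy.

    ``exclude_case``: any missing item voids the construct (not_scorable).
    ``treat_missing_as_zero`` (social support): missing items score 0, unless
    every item is missing, which still voids the construct.
    """
    scores = [
        recode_item(it, record.get(it.item_id), strict=strict, issues=issues)
        for it in construct.items
    ]
    n_missing = sum(s is None for s in scores)
    if construct.missing_policy is MissingPolicy.EXCLUDE_CASE:
        if n_missing > 0:
            return ConstructScore(construct.construct_id, None, BarrierCategory.NOT_SCORABLE, n_missing)
    else:  # treat_missing_as_zero
        if n_missing == len(scores):
            return ConstructScore(construct.construct_id, None, BarrierCategory.NOT_SCORABLE, n_missing)
        scores = [0 if s is None else s for s in scores]
    total = sum(scores)  # type: ignore[arg-type]
    if construct.category_rule.rule_kind in (RuleKind.STYLE_DOMINANCE, RuleKind.DICHOTOMY):
        # Component of a composite: category resolved jointly, placeholder here.
        return ConstructScore(construct.construct_id, total, BarrierCategory.NONE, n_missing)
    return ConstructScore(construct.construct_id, total, categorize(construct, total), n_missing)


def resolve_coping(
    style_sums: Mapping[str, float | None],
    rule: CompositeRule,
) -> tuple[frozenset[str] | None, BarrierCategory]:
    """Resolve the coping composite from per-style sums by dominance.

    The dominant style(s) are the argmax of the present sums.  A single
    dominant style maps through the configured style→category table (problem
    solving is favourable by default); ties (multiple styles) map to the
    multiple-styles category.  Any not-scorable style voids the composite.
    """
    if any(v is None for v in style_sums.values()):
        return None, BarrierCategory.NOT_SCORABLE
    best = max(style_sums.values())
    styles = frozenset(k for k, v in style_sums.items() if v == best)
    if len(styles) > 1:
        return styles, rule.multiple_styles_category
    (style,) = styles
    return styles, rule.style_category.get(style, BarrierCategory.MINOR)


def resolve_locus(
    internal_score: float | None,
    external_score: float | None,
    rule: CompositeRule,
) -> tuple[str | None, BarrierCategory]:
    """Dichotomise locus of control into internal vs external orientation.

    Orientation is internal when the internal item score is at least the
    external item score (ties break to the configured side, internal by
    default); the orientation maps through the configured category table
    (external → minor barrier by default).
    """
    if internal_score is None or external_score is None:
        return None, BarrierCategory.NOT_SCORABLE
    if internal_score > external_score:
        orientation = "internal"
    elif internal_score < external_score:
        orientation = "external"
    else:
        orientation = rule.tie
    return orientation, rule.orientation_category.get(orientation, BarrierCategory.NONE)


def build_profile(
    record: ResponseRecord,
    instrument: InstrumentDefinition,
    *,
    strict: bool = False,
) -> SemasProfile:
    """Score every construct and composite for one respondent.

    Returns a :class:`SemasProfile` with all construct scores, resolved
    coping style(s) and locus orientation, guidance item levels recorded
    verbatim, the barrier count, and any per-item issues collected while
    recoding (lenient mode).
    """
    issues: list[str] = []
    scores: dict[str, ConstructScore] = {}
    for cid, con in instrument.constructs.items():
        if con.role is ConstructRole.GUIDANCE:
            continue
        scores[cid] = score_construct(con, record, strict=strict, issues=issues)

    coping_styles: frozenset[str] | None = None
    locus_orientation: str | None = None
    for comp_id, comp in instrument.composites.items():
        if comp.kind is RuleKind.STYLE_DOMINANCE:
            style_sums = {
                style: scores[member].sum_score
                for style, member in comp.style_labels.items()
            }
            styles, cat = resolve_coping(style_sums, comp)
            coping_styles = styles
            present = [v for v in style_sums.values() if v is not None]
            comp_sum = max(present) if (present and cat is not BarrierCategory.NOT_SCORABLE) else None
            scores[comp_id] = ConstructScore(
                comp_id,
                comp_sum,
                cat,
                sum(v is None for v in style_sums.values()),
            )
        else:  # dichotomy
            int_score = scores[comp.internal].sum_score
            ext_score = scores[comp.external].sum_score
            orientation, cat = resolve_locus(int_score, ext_score, comp)
            locus_orientation = orientation
            comp_sum = None if orientation is None else int_score - ext_score  # type: ignore[operator]
            scores[comp_id] = ConstructScore(
                comp_id, comp_sum, cat, sum(v is None for v in (int_score, ext_score))
            )
        # Components of a scorable composite inherit its category.
        for member in comp.members:
            ms = scores[member]
            if ms.scorable and scores[comp_id].category is not BarrierCategory.NOT_SCORABLE:
                scores[member] = ConstructScore(
                    ms.construct_id, ms.sum_score, scores[comp_id].category, ms.n_missing
                )

    guidance: dict[str, int | None] = {}
    for con in instrument.guidance_constructs():
        item = con.items[0]
        raw = record.get(item.item_id)
        recoded = recode_item(item, raw, strict=strict, issues=issues)
        guidance[con.construct_id] = None if recoded is None else int(raw)  # type: ignore[arg-type]

    units = instrument.barrier_units()
    barrier_count = sum(scores[u].category.is_barrier for u in units)
    not_scorable = tuple(
        u for u in units if scores[u].category is BarrierCategory.NOT_SCORABLE
    )
    return SemasProfile(
        respondent_id=record.respondent_id,
        scores=scores,
        coping_styles=coping_styles,
        locus_orientation=locus_orientation,
        guidance_flags=guidance,
        barrier_count=barrier_count,
        not_scorable=not_scorable,
        issues=tuple(issues),
    )


def score_cohort(
    records: Iterable[ResponseRecord],
    instrument: InstrumentDefinition,
    *,
    strict: bool = False,
) -> list[SemasProfile]:
    """Score a cohort of respondents; order is preserved."""
    return [build_profile(r, instrument, strict=strict) for r in records]
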