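"""Declarative data model for the SeMaS screening instrument.

The instrument — its response scales, items, constructs, barrier cut-offs and
composite rules (coping-style dominance, locus dichotomy) — is described in a
structured YAML/JSON document and loaded into validated, immutable Python
objects.  All scoring downstream is table-driven from this model, so an
alternative banding (e.g. locally calibrated anxiety cut-offs) is a config
change, not a code change.

Schema (version 1)::

    scales:      name -> {levels: [{code, label, score}], collapse: [[codes]]}
    constructs:  id   -> {role, missing_policy, items, category, composite?}
    composites:  id   -> style_dominance or dichotomy wiring

The packaged default definition encodes the published SeMaS rules: 27 items
across seven barrier constructs (self-efficacy, coping P/E/D, depression,
anxiety, locus of control, social support, perceived burden of disease) plus
three guidance items.  The anxiety/depression bands shipped by default are
placeholders (``authoritative: false``); deployments must supply the symptom
questionnaire's own cut-offs.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Mapping, Sequence, Union

import yaml

SCHEMA_VERSION = 1

__all__ = [
    "BarrierCategory",
    "ResponseScale",
    "ItemSpec",
    "CategoryRule",
    "ConstructSpec",
    "CompositeRule",
    "InstrumentDefinition",
    "InstrumentError",
    "InstrumentWarning",
    "load_instrument",
    "default_instrument",
    "attainable_score_range",
]


class InstrumentError(ValueError):
    """An instrument definition failed validation; message names the entity."""


class InstrumentWarning(UserWarning):
    """Non-fatal lint finding in an instrument definition."""


class BarrierCategory(str, enum.Enum):
    """Per-construct classification of a sum score."""

    NONE = "none"
    MINOR = "minor"
    MAJOR = "major"
    NOT_SCORABLE = "not_scorable"

    @property
    def is_barrier(self) -> bool:
        return self in (BarrierCategory.MINOR, BarrierCategory.MAJOR)


@dataclass(frozen=True)
class ResponseScale:
    """An ordered Likert response scale mapping raw codes to scores.

    Scores must be weakly monotone in code; an explicit ``collapse`` group
    declares codes that intentionally share a score (e.g. the coping scale's
    'often' and 'very often/continuously').
    """

    name: str
    levels: tuple[tuple[int, str, int], ...]  # (code, label, score)
    collapse: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise InstrumentError(f"scale {self.name!r}: needs at least 2 levels")
        codes = [lv[0] for lv in self.levels]
        if sorted(set(codes)) != codes:
            raise InstrumentError(f"scale {self.name!r}: codes must be unique and ascending")
        scores = [lv[2] for lv in self.levels]
        if any(s < 0 for s in scores):
            raise InstrumentError(f"scale {self.name!r}: scores must be >= 0")
        if any(b < a for a, b in zip(scores, scores[1:])):
            raise InstrumentError(f"scale {self.name!r}: scores must be weakly monotone in code")

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(lv[0] for lv in self.levels)

    @property
    def score_map(self) -> dict[int, int]:
        return {code: score for code, _, score in self.levels}

    @property
    def min_score(self) -> int:
        return min(lv[2] for lv in self.levels)

    @property
    def max_score(self) -> int:
        return max(lv[2] for lv in self.levels)


@dataclass(frozen=True)
class ItemSpec:
    """One questionnaire item: either Likert (with a scale) or a 0-10 VAS."""

    item_id: str
    construct: str
    scale: ResponseScale | None
    reverse: bool = False
    is_vas: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.is_vas and self.scale is not None:
            raise InstrumentError(f"item {self.item_id!r}: VAS items carry no response scale")
        if not self.is_vas and self.scale is None:
            raise InstrumentError(f"item {self.item_id!r}: non-VAS item needs a scale")

    @property
    def min_score(self) -> int:
        return 0 if self.is_vas else self.scale.min_score  # type: ignore[union-attr]

    @property
    def max_score(self) -> int:
        return 10 if self.is_vas else self.scale.max_score  # type: ignore[union-attr]


class RuleKind(str, enum.Enum):
    BANDED = "banded"
    U_SHAPED = "u_shaped"
    STYLE_DOMINANCE = "style_dominance"
    DICHOTOMY = "dichotomy"
    EXTERNAL_TABLE = "external_table"
    RECORDED = "recorded"  # guidance items: level recorded, never categorised


@dataclass(frozen=True)
class CategoryRule:
    """Banded lookup from a sum score to a barrier category.

    Bands are closed integer intervals and must partition the construct's
    attainable score range.  ``style_dominance`` and ``dichotomy`` rules have
    no bands of their own; those constructs are resolved jointly through a
    :class:`CompositeRule`.
    """

    rule_kind: RuleKind
    bands: tuple[tuple[int, int, BarrierCategory], ...] = ()
    authoritative: bool = True

    def lookup(self, sum_score: int) -> BarrierCategory:
        for lo, hi, cat in self.bands:
            if lo <= sum_score <= hi:
                return cat
        raise InstrumentError(f"sum score {sum_score} outside category bands")

    def validate_partition(self, lo: int, hi: int, owner: str) -> None:
        """Check bands exactly cover [lo, hi] with no gap or overlap."""
        if not self.bands:
            raise InstrumentError(f"construct {owner!r}: rule {self.rule_kind.value} has no bands")
        spans = sorted((b[0], b[1]) for b in self.bands)
        if spans[0][0] != lo:
            raise InstrumentError(
                f"construct {owner!r}: bands start at {spans[0][0]}, attainable minimum is {lo}"
            )
        if spans[-1][1] != hi:
            raise InstrumentError(
                f"construct {owner!r}: bands end at {spans[-1][1]}, attainable maximum is {hi}"
            )
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            if b_lo <= a_hi:
                raise InstrumentError(
                    f"construct {owner!r}: bands [{a_lo},{a_hi}] and [{b_lo},{b_hi}] overlap"
                )
            if b_lo != a_hi + 1:
                raise InstrumentError(
                    f"construct {owner!r}: gap between bands [{a_lo},{a_hi}] and [{b_lo},{b_hi}]"
                )
        if self.rule_kind is RuleKind.U_SHAPED:
            minor_spans = sorted((b[0], b[1]) for b in self.bands if b[2] is BarrierCategory.MINOR)
            if len(minor_spans) != 2 or minor_spans[0][1] + 1 == minor_spans[1][0]:
                raise InstrumentError(
                    f"construct {owner!r}: u_shaped rule needs two non-adjacent minor bands"
                )


class MissingPolicy(str, enum.Enum):
    EXCLUDE_CASE = "exclude_case"
    TREAT_MISSING_AS_ZERO = "treat_missing_as_zero"


class ConstructRole(str, enum.Enum):
    BARRIER = "barrier_construct"
    GUIDANCE = "guidance_item"


@dataclass(frozen=True)
class ConstructSpec:
    """A psychosocial characteristic measured by a small set of items."""

    construct_id: str
    items: tuple[ItemSpec, ...]
    missing_policy: MissingPolicy
    category_rule: CategoryRule
    role: ConstructRole
    composite: str | None = None  # composite this construct feeds, if any

    @property
    def is_vas(self) -> bool:
        return any(it.is_vas for it in self.items)


@dataclass(frozen=True)
class CompositeRule:
    """Joint categorisation over several component constructs.

    ``style_dominance`` (coping): the dominant style(s) are the argmax of the
    per-style sums; a single dominant style maps through ``style_category``
    (problem-solving is favourable by default), multiple tied styles map to
    ``multiple_styles_category``.  ``dichotomy`` (locus of control): internal
    versus external orientation by comparing the two item scores.
    """

    composite_id: str
    kind: RuleKind
    members: tuple[str, ...]
    style_labels: Mapping[str, str] = field(default_factory=dict)  # style -> construct_id
    style_category: Mapping[str, BarrierCategory] = field(default_factory=dict)
    multiple_styles_category: BarrierCategory = BarrierCategory.MINOR
    internal: str = ""
    external: str = ""
    tie: str = "internal"
    orientation_category: Mapping[str, BarrierCategory] = field(default_factory=dict)


@dataclass(frozen=True)
class InstrumentDefinition:
    """A fully validated instrument: scales, items, constructs, composites."""

    name: str
    version: str
    scales: Mapping[str, ResponseScale]
    constructs: Mapping[str, ConstructSpec]
    composites: Mapping[str, CompositeRule]
    schema_version: int = SCHEMA_VERSION

    @property
    def items(self) -> dict[str, ItemSpec]:
        return {it.item_id: it for c in self.constructs.values() for it in c.items}

    @property
    def n_items(self) -> int:
        return sum(len(c.items) for c in self.constructs.values())

    def barrier_units(self) -> list[str]:
        """Categorised units counted in the barrier tally: standalone barrier
        constructs plus one entry per composite."""
        units = [
            c.construct_id
            for c in self.constructs.values()
            if c.role is ConstructRole.BARRIER and c.composite is None
        ]
        return units + list(self.composites)

    def guidance_constructs(self) -> list[ConstructSpec]:
        return [c for c in self.constructs.values() if c.role is ConstructRole.GUIDANCE]

    def to_dict(self) -> dict:
        """Canonical serialisable form (round-trips through load_instrument)."""
        scales = {}
        for name, sc in self.scales.items():
            d: dict = {
                "levels": [
                    {"code": c, "label": lab, "score": s} for c, lab, s in sc.levels
                ]
            }
            if sc.collapse:
                d["collapse"] = [list(g) for g in sc.collapse]
            scales[name] = d
        constructs = {}
        for cid, con in self.constructs.items():
            items = []
            for it in con.items:
                item_d: dict = {"id": it.item_id}
                if it.is_vas:
                    item_d["vas"] = True
                else:
                    item_d["scale"] = it.scale.name  # type: ignore[union-attr]
                if it.reverse:
                    item_d["reverse"] = True
                if it.label:
                    item_d["label"] = it.label
                items.append(item_d)
            cat: dict = {"kind": con.category_rule.rule_kind.value}
            if con.category_rule.bands:
                cat["bands"] = [
                    {"lo": lo, "hi": hi, "category": c.value}
                    for lo, hi, c in con.category_rule.bands
                ]
            if not con.category_rule.authoritative:
                cat["authoritative"] = False
            con_d: dict = {
                "role": con.role.value,
                "missing_policy": con.missing_policy.value,
                "items": items,
                "category": cat,
            }
            if con.composite:
                con_d["composite"] = con.composite
            constructs[cid] = con_d
        composites = {}
        for comp_id, comp in self.composites.items():
            if comp.kind is RuleKind.STYLE_DOMINANCE:
                composites[comp_id] = {
                    "kind": comp.kind.value,
                    "styles": dict(comp.style_labels),
                    "style_category": {k: v.value for k, v in comp.style_category.items()},
                    "multiple_styles_category": comp.multiple_styles_category.value,
                }
            else:
                composites[comp_id] = {
                    "kind": comp.kind.value,
                    "internal": comp.internal,
                    "external": comp.external,
                    "tie": comp.tie,
                    "orientation_category": {
                        k: v.value for k, v in comp.orientation_category.items()
                    },
                }
        return {
            "schema_version": self.schema_version,
            "name": self.name,
            "version": self.version,
            "scales": scales,
            "constructs": constructs,
            "composites": composites,
        }


def attainable_score_range(construct: ConstructSpec) -> tuple[int, int]:
    """Attainable (min, max) sum score for a construct.

    VAS constructs span (0, 10) by definition; otherwise the per-item scale
    minima and maxima are summed.
    """
    if construct.is_vas:
        return (0, 10)
    if not construct.items:
        raise InstrumentError(f"construct {construct.construct_id!r} has no items")
    return (
        sum(it.min_score for it in construct.items),
        sum(it.max_score for it in construct.items),
    )


def _parse_scale(name: str, raw: Mapping) -> ResponseScale:
    try:
        levels = tuple(
            (int(lv["code"]), str(lv.get("label", "")), int(lv["score"]))
            for lv in raw["levels"]
        )
    except (KeyError, TypeError) as exc:
        raise InstrumentError(f"scale {name!r}: malformed levels ({exc})") from exc
    collapse = tuple(tuple(int(c) for c in grp) for grp in raw.get("collapse", ()))
    scale = ResponseScale(name=name, levels=levels, collapse=collapse)
    score_map = scale.score_map
    for grp in collapse:
        unknown = [c for c in grp if c not in score_map]
        if unknown:
            raise InstrumentError(f"scale {name!r}: collapse references unknown codes {unknown}")
        if len({score_map[c] for c in grp}) != 1:
            raise InstrumentError(f"scale {name!r}: collapse group {grp} maps to differing scores")
    return scale


_CATEGORY_KINDS_WITH_BANDS = {RuleKind.BANDED, RuleKind.U_SHAPED, RuleKind.EXTERNAL_TABLE}


def _parse_category(owner: str, raw: Mapping) -> CategoryRule:
    try:
        kind = RuleKind(raw["kind"])
    except (KeyError, ValueError) as exc:
        raise InstrumentError(f"construct {owner!r}: bad category kind ({exc})") from exc
    bands = tuple(
        (int(b["lo"]), int(b["hi"]), BarrierCategory(b["category"]))
        for b in raw.get("bands", ())
    )
    if kind in _CATEGORY_KINDS_WITH_BANDS and not bands:
        raise InstrumentError(
            f"construct {owner!r}: {kind.value} rule requires explicit bands in config"
        )
    return CategoryRule(rule_kind=kind, bands=bands, authoritative=raw.get("authoritative", True))


def load_instrument(source: Union[str, Path, IO[str], Mapping]) -> InstrumentDefinition:
    """Load and validate an instrument definition.

    Parameters
    ----------
    source:
        Path to a YAML/JSON document, an open text stream, a YAML string, or
        an already-parsed mapping.

    Raises
    ------
    InstrumentError
        On unresolved references, duplicated item ids, band gaps/overlaps, or
        any other schema violation; the message names the offending entity.

    Warns
    -----
    InstrumentWarning
        On lint findings, e.g. a social-support construct configured with
        ``exclude_case`` instead of the published missing-as-zero policy.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    elif isinstance(source, Path):
        doc = yaml.safe_load(source.read_text(encoding="utf-8"))
    elif isinstance(source, str):
        p = Path(source)
        # Heuristic: multi-line strings are documents, short ones are paths.
        if "\n" not in source and p.exists():
            doc = yaml.safe_load(p.read_text(encoding="utf-8"))
        else:
            doc = yaml.safe_load(source)
    else:
        doc = yaml.safe_load(source.read())
    if not isinstance(doc, Mapping):
        raise InstrumentError("instrument config did not parse to a mapping")

    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise InstrumentError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")

    scales = {name: _parse_scale(name, raw) for name, raw in doc.get("scales", {}).items()}

    constructs: dict[str, ConstructSpec] = {}
    seen_items: set[str] = set()
    for cid, raw in doc.get("constructs", {}).items():
        items = []
        for item_raw in raw.get("items", ()):
            item_id = str(item_raw["id"])
            if item_id in seen_items:
                raise InstrumentError(f"duplicated item_id {item_id!r}")
            seen_items.add(item_id)
            is_vas = bool(item_raw.get("vas", False))
            scale = None
            if not is_vas:
                scale_name = item_raw.get("scale")
                if scale_name not in scales:
                    raise InstrumentError(
                        f"item {item_id!r}: unresolved scale reference {scale_name!r}"
                    )
                scale = scales[scale_name]
            items.append(
                ItemSpec(
                    item_id=item_id,
                    construct=cid,
                    scale=scale,
                    reverse=bool(item_raw.get("reverse", False)),
                    is_vas=is_vas,
                    label=str(item_raw.get("label", "")),
                )
            )
        if not items:
            raise InstrumentError(f"construct {cid!r} has no items")
        try:
            policy = MissingPolicy(raw.get("missing_policy", "exclude_case"))
            role = ConstructRole(raw.get("role", "barrier_construct"))
        except ValueError as exc:
            raise InstrumentError(f"construct {cid!r}: {exc}") from exc
        default_kind = "recorded" if role is ConstructRole.GUIDANCE else "banded"
        rule = _parse_category(cid, raw.get("category", {"kind": default_kind}))
        con = ConstructSpec(
            construct_id=cid,
            items=tuple(items),
            missing_policy=policy,
            category_rule=rule,
            role=role,
            composite=raw.get("composite"),
        )
        if rule.rule_kind in _CATEGORY_KINDS_WITH_BANDS:
            lo, hi = attainable_score_range(con)
            rule.validate_partition(lo, hi, cid)
        constructs[cid] = con

    composites: dict[str, CompositeRule] = {}
    for comp_id, raw in doc.get("composites", {}).items():
        try:
            kind = RuleKind(raw["kind"])
        except (KeyError, ValueError) as exc:
            raise InstrumentError(f"composite {comp_id!r}: bad kind ({exc})") from exc
        if kind is RuleKind.STYLE_DOMINANCE:
            styles = {str(k): str(v) for k, v in raw.get("styles", {}).items()}
            for style, member in styles.items():
                if member not in constructs:
                    raise InstrumentError(
                        f"composite {comp_id!r}: style {style!r} references "
                        f"unknown construct {member!r}"
                    )
            composites[comp_id] = CompositeRule(
                composite_id=comp_id,
                kind=kind,
                members=tuple(styles.values()),
                style_labels=styles,
                style_category={
                    k: BarrierCategory(v) for k, v in raw.get("style_category", {}).items()
                },
                multiple_styles_category=BarrierCategory(
                    raw.get("multiple_styles_category", "minor")
                ),
            )
        elif kind is RuleKind.DICHOTOMY:
            internal, external = raw.get("internal"), raw.get("external")
            for member in (internal, external):
                if member not in constructs:
                    raise InstrumentError(
                        f"composite {comp_id!r}: references unknown construct {member!r}"
                    )
            composites[comp_id] = CompositeRule(
                composite_id=comp_id,
                kind=kind,
                members=(internal, external),
                internal=internal,
                external=external,
                tie=str(raw.get("tie", "internal")),
                orientation_category={
                    k: BarrierCategory(v)
                    for k, v in raw.get("orientation_category", {}).items()
                },
            )
        else:
            raise InstrumentError(f"composite {comp_id!r}: kind {kind.value} not allowed here")

    for cid, con in constructs.items():
        if con.composite is not None and con.composite not in composites:
            raise InstrumentError(
                f"construct {cid!r}: unresolved composite reference {con.composite!r}"
            )

    # Lint: the published social-support rule treats missing items as zero.
    ss = constructs.get("social_support")
    if ss is not None and ss.missing_policy is not MissingPolicy.TREAT_MISSING_AS_ZERO:
        warnings.warn(
            "social_support uses exclude_case; the published rule treats missing "
            "subitems as 'not applicable' (scored 0)",
            InstrumentWarning,
            stacklevel=2,
        )

    return InstrumentDefinition(
        name=str(doc.get("name", "instrument")),
        version=str(doc.get("version", "0")),
        scales=scales,
        constructs=constructs,
        composites=composites,
        schema_version=version,
    )


def default_instrument() -> InstrumentDefinition:
    """The packaged default SeMaS definition (27 items, 7 barrier constructs)."""
    with resources.files("semas.data").joinpath("default_instrument.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return load_instrument(fh)
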