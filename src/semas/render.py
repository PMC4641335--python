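"""Render the SeMaS graphic profile: a one-glance per-respondent view placing
each construct's score inside its no/minor/major barrier zone.

The published profile is a clinician-facing bar chart; the exact visual
encoding is not standardised, so this renderer is a faithful-in-spirit
redesign with two formats:

* ``text`` — fixed-width ASCII, deterministic byte-for-byte (golden-file
  testable, locale-independent);
* ``svg``  — resolution-independent vector graphic with coloured barrier
  zones and a marker per construct.

The renderer never re-bands scores: every marker's category is taken verbatim
from the scored profile, and zone geometry is derived from the instrument's
category bands.
"""

from __future__ import annotations

from dataclasses import dataclass

from .instrument import (
    BarrierCategory,
    InstrumentDefinition,
    RuleKind,
    attainable_score_range,
)
from .scoring import SemasProfile

__all__ = ["ProfileRow", "ProfileRendering", "layout_profile", "render_profile"]

# Fixed default row order; configurable via `order=`.
DEFAULT_ORDER = (
    "burden",
    "self_efficacy",
    "locus",
    "anxiety",
    "depression",
    "coping",
    "social_support",
)

_DISPLAY = {
    "burden": "perceived burden",
    "self_efficacy": "self-efficacy",
    "locus": "locus of control",
    "anxiety": "anxiety",
    "depression": "depression",
    "coping": "coping style",
    "social_support": "social support",
    "computer_skills": "computer skills",
    "group_functioning": "functioning in groups",
    "self_monitoring_willingness": "willing to self-monitor",
}

_ZONE_COLOUR = {
    BarrierCategory.NONE: "#66bb6a",
    BarrierCategory.MINOR: "#ffb74d",
    BarrierCategory.MAJOR: "#e57373",
}


@dataclass(frozen=True)
class ProfileRow:
    """One rendered construct: marker position and zone geometry in [0, 1]."""

    construct_id: str
    label: str
    sum_score: float | None
    score_range: tuple[float, float]
    position: float | None  # (sum - min) / (max - min); None if not scorable
    category: BarrierCategory
    zones: tuple[tuple[float, float, BarrierCategory], ...]
    annotation: str = ""  # e.g. dominant coping style, locus orientation


@dataclass(frozen=True)
class ProfileRendering:
    respondent_id: str
    rows: tuple[ProfileRow, ...]
    guidance: tuple[tuple[str, str, int | None], ...]


def _zones_for(instrument: InstrumentDefinition, cid: str):
    """Normalised zone spans from a construct's category bands.

    Band edges sit at half-integers so integer scores fall strictly inside
    their band's zone.
    """
    con = instrument.constructs.get(cid)
    if con is None or con.category_rule.rule_kind not in (
        RuleKind.BANDED,
        RuleKind.U_SHAPED,
        RuleKind.EXTERNAL_TABLE,
    ):
        return ()
    lo, hi = attainable_score_range(con)
    span = hi - lo or 1
    zones = []
    for b_lo, b_hi, cat in sorted(con.category_rule.bands):
        start = max(0.0, (b_lo - 0.5 - lo) / span)
        end = min(1.0, (b_hi + 0.5 - lo) / span)
        zones.append((start, end, cat))
    return tuple(zones)


def layout_profile(
    profile: SemasProfile,
    instrument: InstrumentDefinition,
    order: tuple[str, ...] = DEFAULT_ORDER,
) -> ProfileRendering:
    """Compute the geometric layout (rows, positions, zones) for a profile."""
    rows = []
    for cid in order:
        score = profile.scores.get(cid)
        if score is None:
            continue
        annotation = ""
        if cid in instrument.composites:
            comp = instrument.composites[cid]
            if comp.kind is RuleKind.STYLE_DOMINANCE:
                members = [instrument.constructs[m] for m in comp.members]
                ranges = [attainable_score_range(m) for m in members]
                lo, hi = min(r[0] for r in ranges), max(r[1] for r in ranges)
                if profile.coping_styles:
                    annotation = "+".join(sorted(profile.coping_styles))
            else:
                int_lo, int_hi = attainable_score_range(instrument.constructs[comp.internal])
                ext_lo, ext_hi = attainable_score_range(instrument.constructs[comp.external])
                lo, hi = int_lo - ext_hi, int_hi - ext_lo
                if profile.locus_orientation:
                    annotation = profile.locus_orientation
        else:
            lo, hi = attainable_score_range(instrument.constructs[cid])
        position = None
        if score.scorable:
            position = (float(score.sum_score) - lo) / ((hi - lo) or 1)
        rows.append(
            ProfileRow(
                construct_id=cid,
                label=_DISPLAY.get(cid, cid),
                sum_score=None if score.sum_score is None else float(score.sum_score),
                score_range=(float(lo), float(hi)),
                position=position,
                category=score.category,
                zones=_zones_for(instrument, cid),
                annotation=annotation,
            )
        )
    guidance = tuple(
        (gid, _DISPLAY.get(gid, gid), level)
        for gid, level in profile.guidance_flags.items()
    )
    return ProfileRendering(respondent_id=profile.respondent_id, rows=rows, guidance=guidance)


_TRACK = 21  # characters in the ASCII track


def _format_score(row: ProfileRow) -> str:
    if row.sum_score is None:
        return "-"
    lo, hi = row.score_range
    val = f"{row.sum_score:g}"
    return f"{val}/{hi:g}" if lo == 0 else f"{val:>3}"


def _render_text(r: ProfileRendering) -> str:
    lines = [f"SeMaS profile: {r.respondent_id}", "=" * (16 + len(r.respondent_id))]
    for row in r.rows:
        label = row.label + (f" ({row.annotation})" if row.annotation else "")
        if row.position is None:
            lines.append(f"{label:<28}{'-':>6}  not scorable")
            continue
        track = ["."] * _TRACK
        for start, end, cat in row.zones:
            mark = {"none": ".", "minor": "-", "major": "="}[cat.value]
            i0 = int(round(start * (_TRACK - 1)))
            i1 = int(round(end * (_TRACK - 1)))
            for i in range(i0, i1 + 1):
                track[i] = mark
        track[int(round(row.position * (_TRACK - 1)))] = "#"
        lines.append(
            f"{label:<28}{_format_score(row):>6}  [{''.join(track)}]  {row.category.value}"
        )
    lines.append("guidance:")
    for _, label, level in r.guidance:
        lines.append(f"  {label}: {'-' if level is None else level}")
    return "\n".join(lines) + "\n"


def _render_svg(r: ProfileRendering) -> str:
    row_h, track_x, track_w, pad = 34, 220, 360, 10
    height = pad * 2 + row_h * (len(r.rows) + len(r.guidance) + 2)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="640" height="{height}" '
        f'font-family="sans-serif" font-size="13">',
        f'<text x="{pad}" y="{pad + 14}" font-size="15" font-weight="bold">'
        f"SeMaS profile: {r.respondent_id}</text>",
    ]
    y = pad + row_h
    for row in r.rows:
        cy = y + row_h // 2
        label = row.label + (f" ({row.annotation})" if row.annotation else "")
        parts.append(f'<text x="{pad}" y="{cy + 4}">{label}</text>')
        if row.zones:
            for start, end, cat in row.zones:
                x0 = track_x + start * track_w
                parts.append(
                    f'<rect x="{x0:.1f}" y="{cy - 8}" width="{(end - start) * track_w:.1f}" '
                    f'height="16" fill="{_ZONE_COLOUR[cat]}" rx="3"/>'
                )
        else:
            fill = _ZONE_COLOUR.get(row.category, "#cccccc")
            parts.append(
                f'<rect x="{track_x}" y="{cy - 8}" width="{track_w}" height="16" '
                f'fill="{fill}" opacity="0.45" rx="3"/>'
            )
        if row.position is None:
            parts.append(
                f'<text x="{track_x + track_w / 2:.1f}" y="{cy + 4}" '
                f'text-anchor="middle" fill="#666">not scorable</text>'
            )
        else:
            mx = track_x + row.position * track_w
            parts.append(
                f'<circle cx="{mx:.1f}" cy="{cy}" r="6" fill="#1a1a1a"/>'
                f'<text x="{track_x + track_w + 12}" y="{cy + 4}">{_format_score(row)}</text>'
            )
        y += row_h
    y += row_h // 2
    parts.append(f'<text x="{pad}" y="{y}" font-weight="bold">Guidance</text>')
    for _, label, level in r.guidance:
        y += row_h
        shown = "-" if level is None else str(level)
        parts.append(f'<text x="{pad}" y="{y}">{label}: {shown}</text>')
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_profile(
    profile: SemasProfile,
    instrument: InstrumentDefinition,
    fmt: str = "text",
    order: tuple[str, ...] = DEFAULT_ORDER,
) -> str:
    """Render a scored profile to ``text`` or ``svg``.

    Raises ``ValueError`` for an unknown format.
    """
    layout = layout_profile(profile, instrument, order=order)
    if fmt == "text":
        return _render_text(layout)
    if fmt == "svg":
        return _render_svg(layout)
    raise ValueError(f"unknown profile format {fmt!r} (expected 'text' or 'svg')")
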