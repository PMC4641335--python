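# Default SeMaS instrument definition (schema v1).
#
# Item wordings are not reproduced here; items are identified by construct +
# ordinal and carry an optional short label.  Scoring is wording-independent.
#
# The anxiety and depression barrier cut-offs below are PLACEHOLDERS marked
# non-authoritative: the instrument defers to the source symptom questionnaire
# (4DSQ) for those categories and a validation deployment must supply its own
# external_table bands.
schema_version: 1
name: SeMaS
version: "1.0"

scales:
  agree4:
    # 4-point agreement scale, completely false .. completely true
    levels:
      - {code: 1, label: completely false, score: 0}
      - {code: 2, label: somewhat false, score: 1}
      - {code: 3, label: somewhat true, score: 2}
      - {code: 4, label: completely true, score: 3}
  freq5_coping:
    # 5-point frequency scale; 'often' collapses onto the top score so the
    # item still spans 0-3 like the 4-point source scale
    levels:
      - {code: 1, label: never, score: 0}
      - {code: 2, label: sometimes, score: 1}
      - {code: 3, label: regularly, score: 2}
      - {code: 4, label: often, score: 3}
      - {code: 5, label: very often/continuously, score: 3}
    collapse: [[4, 5]]
  freq5:
    # 5-point frequency scale scored linearly (depression/anxiety items)
    levels:
      - {code: 1, label: never, score: 0}
      - {code: 2, label: sometimes, score: 1}
      - {code: 3, label: regularly, score: 2}
      - {code: 4, label: often, score: 3}
      - {code: 5, label: very often/continuously, score: 4}
  support5:
    # social-support scale: no / completely false / somewhat false -> 0,
    # somewhat true -> 1, completely true -> 2
    levels:
      - {code: 1, label: "no", score: 0}
      - {code: 2, label: completely false, score: 0}
      - {code: 3, label: somewhat false, score: 0}
      - {code: 4, label: somewhat true, score: 1}
      - {code: 5, label: completely true, score: 2}
    collapse: [[1, 2, 3]]

constructs:
  self_efficacy:
    role: barrier_construct
    missing_policy: exclude_case
    items:
      - {id: se_1, scale: agree4}
      - {id: se_2, scale: agree4}
    category:
      kind: banded
      bands:
        - {lo: 4, hi: 6, category: none}
        - {lo: 2, hi: 3, category: minor}
        - {lo: 0, hi: 1, category: major}
  coping_P:
    role: barrier_construct
    composite: coping
    missing_policy: exclude_case
    items:
      - {id: cop_p_1, scale: freq5_coping}
      - {id: cop_p_2, scale: freq5_coping}
    category: {kind: style_dominance}
  coping_E:
    role: barrier_construct
    composite: coping
    missing_policy: exclude_case
    items:
      - {id: cop_e_1, scale: freq5_coping}
      - {id: cop_e_2, scale: freq5_coping}
    category: {kind: style_dominance}
  coping_D:
    role: barrier_construct
    composite: coping
    missing_policy: exclude_case
    items:
      - {id: cop_d_1, scale: freq5_coping}
      - {id: cop_d_2, scale: freq5_coping}
    category: {kind: style_dominance}
  depression:
    role: barrier_construct
    missing_policy: exclude_case
    items:
      - {id: dep_1, scale: freq5}
      - {id: dep_2, scale: freq5}
      - {id: dep_3, scale: freq5}
    category:
      kind: external_table
      authoritative: false
      bands:
        - {lo: 0, hi: 2, category: none}
        - {lo: 3, hi: 5, category: minor}
        - {lo: 6, hi: 12, category: major}
  anxiety:
    role: barrier_construct
    missing_policy: exclude_case
    items:
      - {id: anx_1, scale: freq5}
      - {id: anx_2, scale: freq5}
      - {id: anx_3, scale: freq5}
      - {id: anx_4, scale: freq5}
    category:
      kind: external_table
      authoritative: false
      bands:
        - {lo: 0, hi: 3, category: none}
        - {lo: 4, hi: 7, category: minor}
        - {lo: 8, hi: 16, category: major}
  locus_internal:
    role: barrier_construct
    composite: locus
    missing_policy: exclude_case
    items:
      - {id: loc_int, scale: agree4}
    category: {kind: dichotomy}
  locus_external:
    role: barrier_construct
    composite: locus
    missing_policy: exclude_case
    items:
      - {id: loc_ext, scale: agree4}
    category: {kind: dichotomy}
  social_support:
    role: barrier_construct
    missing_policy: treat_missing_as_zero
    items:
      - {id: ss_1, scale: support5}
      - {id: ss_2, scale: support5}
      - {id: ss_3, scale: support5}
      - {id: ss_4, scale: support5}
      - {id: ss_5, scale: support5}
      - {id: ss_6, scale: support5, label: support from neighbours}
    category:
      kind: banded
      bands:
        - {lo: 3, hi: 12, category: none}
        - {lo: 2, hi: 2, category: minor}
        - {lo: 0, hi: 1, category: major}
  burden:
    role: barrier_construct
    missing_policy: exclude_case
    items:
      - {id: burden, vas: true, label: perceived burden of disease (VAS 0-10)}
    category:
      kind: u_shaped
      bands:
        - {lo: 0, hi: 2, category: minor}
        - {lo: 3, hi: 7, category: none}
        - {lo: 8, hi: 10, category: minor}
  computer_skills:
    role: guidance_item
    missing_policy: exclude_case
    items:
      - {id: guide_computer, scale: agree4}
  group_functioning:
    role: guidance_item
    missing_policy: exclude_case
    items:
      - {id: guide_groups, scale: agree4}
  self_monitoring_willingness:
    role: guidance_item
    missing_policy: exclude_case
    items:
      - {id: guide_selfmonitor, scale: agree4}

composites:
  coping:
    kind: style_dominance
    styles: {P: coping_P, E: coping_E, D: coping_D}
    # which single dominant style counts as a barrier; ties/multiple -> minor
    style_category: {P: none, E: minor, D: minor}
    multiple_styles_category: minor
  locus:
    kind: dichotomy
    internal: locus_internal
    external: locus_external
    tie: internal
    orientation_category: {internal: none, external: minor}
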