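SeMaS profile: demo-001
========================
perceived burden            8.5/10  [-----..........--#---]  minor
self-efficacy                  2/6  [=====--#----.........]  minor
locus of control (external)     -2  [...#.................]  minor
anxiety                       5/16  [....--#--============]  minor
depression                    1/12  [..#.-----============]  none
coping style (P)               6/6  [....................#]  none
social support                3/12  [==--.#...............]  none
guidance:
  computer skills: 4
  functioning in groups: 2
  willing to self-monitor: -
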