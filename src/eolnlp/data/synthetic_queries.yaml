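# Query groups matching the synthetic generator's planted phrase groups.
# Phrase syntax: quoted phrase with optional ~slop suffix; fuzzy
# per-token matching (<=1 edit on tokens of >=5 characters) is on by
# default, absorbing planted typographical corruption.
date_range:
  start: 2018-10-01
  end: 2019-09-30
groups:
  - label: ceiling_of_care
    phrases:
      - '"ceiling of care"'
      - '"ceilings of care"'
      - '"ceiling of treatment"'
      - '"ceilings of treatment"'
      - '"ceiling of rx"'
      - '"limit of care"'
      - '"limits of care"'
      - '"ward based care"'
      - '"escalation beyond ward"'
      - '"treatment escalation plan"'
  - label: end_of_life
    phrases:
      - '"end of life care"'
      - '"end of life"'
      - '"eol care"'
      - '"terminal care"'
      - '"palliative care only"'
      - '"palliative treatments only"'
      - '"palliative input"'
      - '"liverpool care pathway"'
      - '"withdrawal of care"'
      - '"withdrawal of treatment"'
  - label: lst_limitation
    phrases:
      - '"not for intubation"'
      - '"not for itu"'
      - '"not for icu"'
      - '"not for critical care"'
      - '"not for resuscitation"'
      - '"not for cpr"'
      - '"not for inotropes"'
      - '"not for niv"'
      - '"not for hdu"'
      - '"not for escalation"'
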