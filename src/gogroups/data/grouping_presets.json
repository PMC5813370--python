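[
  {
    "name": "participant_OR_reg_participant",
    "subproperties": ["has_participant"],
    "chains": [["regulates", "has_participant"]],
    "reflexive": false,
    "description_template": "A process in which a {filler} participates, or that regulates a process in which a {filler} participates."
  },
  {
    "name": "occurs_in_OR_has_participant",
    "subproperties": ["occurs_in", "has_participant"],
    "chains": [],
    "reflexive": false,
    "description_template": "A process that occurs in a {filler}, or in which a {filler} participates."
  },
  {
    "name": "structure_grouping",
    "subproperties": ["part_of", "results_in_organization_of", "has_participant"],
    "chains": [],
    "reflexive": true,
    "description_template": "A {filler} OR part of a {filler} OR a process that results in organisation of a {filler} OR that has a {filler} as a participant."
  },
  {
    "name": "cell_grouping",
    "subproperties": ["part_of", "has_participant", "occurs_in", "results_in_development_of"],
    "chains": [],
    "reflexive": false,
    "description_template": "Some part of a {filler}, or some process in which: a {filler} participates or that occurs in a {filler} or which results in the developmental progression of a cell that will form a {filler}."
  }
]
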