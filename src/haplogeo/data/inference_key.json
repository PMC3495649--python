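{
  "version": "2004-lite.1",
  "comment": "Decision tree over aggregate Dc/Dn significance patterns of a nesting group. Questions name predicates evaluated on the pattern; terminal nodes carry the conclusion category.",
  "root": "1",
  "steps": {
    "1": {
      "question": "any_significant",
      "yes": "2",
      "no": {"conclusion": "inconclusive: cannot reject panmixia (no significant geographic association)"}
    },
    "2": {
      "question": "restricted_dc",
      "yes": "3",
      "no": "11"
    },
    "3": {
      "question": "reversed_dn",
      "yes": "5",
      "no": "4"
    },
    "4": {
      "question": "ranges_disjoint",
      "yes": "9",
      "no": {"conclusion": "restricted gene flow with isolation by distance"}
    },
    "9": {
      "question": "ranges_disjoint",
      "yes": {"conclusion": "allopatric fragmentation"},
      "no": {"conclusion": "past fragmentation"}
    },
    "5": {
      "question": "long_distance_dn",
      "yes": {"conclusion": "restricted gene flow/dispersal but with some long-distance dispersal over intermediate areas not occupied by the species; or past gene flow followed by extinction of intermediate populations"},
      "no": {"conclusion": "inconclusive: cannot discriminate restricted gene flow from long-distance dispersal"}
    },
    "11": {
      "question": "expansion_dc",
      "yes": "12",
      "no": {"conclusion": "inconclusive geographic pattern"}
    },
    "12": {
      "question": "ranges_contiguous",
      "yes": {"conclusion": "contiguous range expansion"},
      "no": "13"
    },
    "13": {
      "question": "ranges_disjoint",
      "yes": {"conclusion": "long-distance colonization possibly coupled with subsequent fragmentation; or past fragmentation followed by range expansion"},
      "no": {"conclusion": "inconclusive geographic pattern"}
    }
  }
}
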