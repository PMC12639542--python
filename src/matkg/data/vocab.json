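{
  "specific_materials": [
    ["MBG-58S", "glass"],
    ["MBG-85S", "glass"],
    ["SiO2-CaO", "glass"],
    ["58S", "bioglass", "powder"],
    ["80S15C", "bioglass"]
  ],
  "general_materials": [
    ["bioactive", "glasses"],
    ["mesoporous", "glasses"]
  ],
  "aliases": [
    ["the", "sol"],
    ["the", "mixture"],
    ["the", "gel"]
  ],
  "steps": [
    {"verb": "dissolved",
     "reagents": [["ethanol"], ["deionized", "water"]],
     "values": [["30", "min"], ["1", "h"]]},
    {"verb": "stirred",
     "reagents": [["P123"], ["F127"]],
     "values": [["24", "h"], ["12", "h"]]},
    {"verb": "aged",
     "reagents": [],
     "values": [["48", "h"], ["36", "h"]]},
    {"verb": "dried",
     "reagents": [],
     "values": [["60", "°C"], ["80", "°C"]]},
    {"verb": "calcined",
     "reagents": [],
     "values": [["600", "°C"], ["700", "°C"]]}
  ],
  "prep_reagents": [
    {"name": ["TEP"], "amounts": [["5", "ml"], ["4", "ml"]]},
    {"name": ["TEOS"], "amounts": [["10", "ml"]]},
    {"name": ["citric", "acid"], "amounts": [["50", "g"]]},
    {"name": ["calcium", "nitrate"], "amounts": [["2", "g"], ["3", "g"]]}
  ],
  "properties": [
    {"name": ["SSA"], "values": [["350", "m2/g"], ["420", "m2/g"]]},
    {"name": ["pore", "size"], "values": [["5", "nm"], ["8", "nm"]]},
    {"name": ["zeta", "potential"], "values": [["24", "mV"]]}
  ],
  "distractor_reagents": [["acetone"], ["toluene"], ["glycerol"]],
  "distractor_values": [["7", "days"], ["100", "rpm"]]
}
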