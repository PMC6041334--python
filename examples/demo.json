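{
 "seed": 1,
 "conditions": [
  {"name": "untreated"},
  {"name": "olaparib",
   "drug_effects": {"s_phase_gh2ax_fold": 4.0, "edu_suppression": 0.3,
                    "par_suppression": 0.8, "s_g2_accumulation_shift": 0.1}},
  {"name": "olaparib_MMS_preextracted", "pre_extraction": true,
   "drug_effects": {"s_phase_gh2ax_fold": 6.0, "trapping_fold": 3.0,
                    "edu_suppression": 0.3, "par_suppression": 0.8}},
  {"name": "olaparib_ATRi",
   "drug_effects": {"s_phase_gh2ax_fold": 4.0, "mitotic_gh2ax_fold": 5.0}}
 ],
 "generator": {
  "n_cells": 400,
  "markers": ["gh2ax", "edu", "cyclin_a", "h3ps10", "parp1", "par"],
  "foci_models": {"rad51": {"rate_s": 3.0, "rate_other": 0.1,
                            "couple_to_gh2ax": true}}
 },
 "render": {"shape": [1024, 1024]},
 "cells_per_field": 200,
 "channel_map": {"dapi": "dapi", "gh2ax": "gh2ax", "edu": "edu",
                 "cyclin_a": "cyclin_a", "h3ps10": "h3ps10",
                 "parp1": "parp1", "par": "par", "rad51": "rad51"},
 "staging": {"markers": ["dapi", "edu", "cyclin_a", "h3ps10"]},
 "quantify": {"marker": "gh2ax", "reference": "untreated"},
 "foci_channels": ["rad51"]
}
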