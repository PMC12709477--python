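"""Generate the synthetic study inputs for every downstream driver.

Emulates the data the pipeline expects: a 4-subgroup, 160-sample expression
cohort with 16 planted marker gene sets and two-platform monotone
distortion; 1000 xenograft read pairs of known origin; three foreground and
two background DE contrasts with planted shared/exclusive genes; and a
two-chromosome synthetic genome with gene models and promoter-planted
peaks. Ground truth (marker map, read origins, DE truth) is written next to
the data so later drivers can score themselves.
"""

import importlib
import json

from mbsub.pipeline import run_simulate

cfg_mod = importlib.import_module("00_config")

paths = run_simulate(cfg_mod.CONFIG, cfg_mod.INPUTS, seed=cfg_mod.SEED)
marker_map = json.loads((cfg_mod.INPUTS / "marker_map.json").read_text())
print(f"wrote {len(paths)} input files to {cfg_mod.INPUTS}")
print(f"planted marker sets per subgroup: "
      f"{ {k: len(v) for k, v in marker_map.items()} }")
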