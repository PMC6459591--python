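"""Rank candidate stimuli with the expert 2AFC protocol.

Four observers each complete four sessions; every session pairs all
candidates once, so each image accumulates 16 comparisons.  Images winning
strictly more than the cut-off of 9 survive to the naming study.
"""

import numpy as np

from faogen import select_top_third, simulate_2afc, tally_wins

rng = np.random.default_rng(1)
ids = [f"img{i:03d}" for i in range(48)]
# planted "objectness": later images look more like single objects
strengths = {img: 0.5 + i for i, img in enumerate(ids)}

records = simulate_2afc(ids, strengths, n_observers=4, n_sessions=4, rng=rng)
tally = tally_wins(records)
print(f"trials: {len(records)}; exposures per image: "
      f"{tally['exposures'].unique().tolist()}")

kept = select_top_third(tally, cutoff=9)
print(f"retained {len(kept)}/{len(ids)} images with > 9 wins")
mean_kept = np.mean([strengths[k] for k in kept])
mean_all = np.mean(list(strengths.values()))
print(f"mean planted strength, retained vs all: {mean_kept:.1f} vs {mean_all:.1f}")
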