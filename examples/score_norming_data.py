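"""Score simulated Yes/No + Naming norming data.

Simulates raters with planted per-image recognizability and label mixtures,
applies the participant exclusion rules, then recomputes recognizability and
semantic stability per image and runs the final-set selection filters.
"""

import numpy as np
import pandas as pd

from faogen import (ObserverModel, exclude_participants, recognizability,
                    select_final_set, simulate_responses, stability_table)

rng = np.random.default_rng(7)
ids = [f"s{i:02d}" for i in range(30)]
p_yes = {img: float(p) for img, p in zip(ids, rng.uniform(0.2, 0.9, len(ids)))}
labels = {img: (["whale", "key", "house"], [0.75, 0.15, 0.10]) for img in ids}
model = ObserverModel(p_yes=p_yes, label_distribution=labels,
                      timeout_rate=0.03, refusal_rate=0.05)

yesno, naming = simulate_responses(ids, model, n_participants=60,
                                   images_per_participant=20, rng=rng)

retained, summary = exclude_participants(yesno)
print(f"retained {len(retained)}/{summary.shape[0]} participants")
yesno = yesno[yesno["participant"].isin(retained)]
naming = naming[naming["participant"].isin(retained)]

rec = recognizability(yesno)
stab = stability_table(naming)
table = stab.join(rec)
print(table[["recognizability", "stability", "dominant_major",
             "n_labels"]].head(8).round(2))

table["n_features"] = 120          # stimulus bookkeeping joined in practice
table["adjusted_fraction"] = 0.02  # from simplify_orientations
final = select_final_set(table.dropna(subset=["stability"]))
print(f"final set after the deterministic discard rules: "
      f"{len(final)}/{len(table)} images")
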