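"""Train both ranking stages on planted hairpins and predict held-out sites.

Simulates 150 training and 40 test hairpins, trains the Drosha forest (21
energy/length features) and the Dicer forest (42 structural features) and
reports within-d-nt accuracy on the held-out set. The baselines are what a
uniformly random pick among each record's candidates would score.
"""

import numpy as np

from mircleave import dicer, drosha, pipeline
from mircleave.config import Config
from mircleave.synthetic import GenParams, make_dataset

cfg = Config(seed=0)
train = make_dataset(GenParams(seed=7, n=150, signal_strength=0.8)).records
test = make_dataset(GenParams(seed=8, n=40, signal_strength=0.8)).records
for r in train + test:
    r.structure = None  # predict from sequence alone

dmodel = pipeline.train_drosha_stage(train, cfg)
cmodel = pipeline.train_dicer_stage(train, cfg)

exact = within2 = 0
baseline = []
dicer_exact = dicer_within2 = n_dicer = 0
for rec in test:
    hp = drosha.prepare(rec)
    truth_d, truth_c_abs = rec.truth
    cut, score, cands = drosha.predict_drosha(hp, dmodel)
    exact += cut.position == truth_d
    within2 += abs(cut.position - truth_d) <= 2
    baseline.append(1 / len(cands))
    pm = dicer.build_premirna(hp, truth_d, refold=True)
    if pm.irregular:
        continue
    truth_c = truth_c_abs - truth_d
    dcut, _, _ = dicer.predict_dicer(pm, cmodel)
    dicer_exact += dcut.position == truth_c
    dicer_within2 += abs(dcut.position - truth_c) <= 2
    n_dicer += 1

n = len(test)
print(f"Drosha: exact {exact / n:.2f}, within 2 nt {within2 / n:.2f} "
      f"(random-argmax baseline {np.mean(baseline):.2f})")
print(f"Dicer:  exact {dicer_exact / n_dicer:.2f}, "
      f"within 2 nt {dicer_within2 / n_dicer:.2f} (baseline 0.10)")
print("\nA within-2-nt rate several times the baseline means the forests")
print("recover the planted cleavage geometry, not just candidate counts.")
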