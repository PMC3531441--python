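"""Average stack-face energy patterns and their correlation across cohorts.

Builds two disjoint cohorts of planted hairpins, averages each cohort's
face-energy window downstream of the true Drosha cut, and reports the
Pearson correlation of the two mean patterns over faces 0..19 — the
cohort analogue of comparing species-level energy patterns. A high-signal
cohort pair correlates strongly; a random-composition pair does not have
to.
"""

from mircleave import drosha
from mircleave.energy import average_pattern, pattern_correlation, profile_window
from mircleave.synthetic import GenParams, plant_hairpin


def cohort_pattern(gen_seed: int, signal: float, n: int = 50):
    windows = []
    for i in range(n):
        rec = plant_hairpin(GenParams(seed=gen_seed, signal_strength=signal), seed=i)
        hp = drosha.prepare(rec)
        d = drosha.derive_drosha_truth(hp).position
        windows.append(profile_window(hp.profile, d, lo=0, hi=19))
    return average_pattern(windows)

strong_a = cohort_pattern(11, signal=1.0)
strong_b = cohort_pattern(12, signal=1.0)
random_a = cohort_pattern(13, signal=0.0)

r_strong = pattern_correlation(strong_a, strong_b)
r_cross = pattern_correlation(strong_a, random_a)

print("mean face energies (kcal/mol), faces 0..19 downstream of the cut:")
print("signal cohort A:", " ".join(f"{e:5.2f}" for e in strong_a))
print("signal cohort B:", " ".join(f"{e:5.2f}" for e in strong_b))
print(f"\nPearson r (signal vs signal): {r_strong:.3f}")
print(f"Pearson r (signal vs random): {r_cross:.3f}")
print("\nShared planting templates produce a conserved energy pattern, the")
print("property that lets one species' model generalize to another.")
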