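# Methods

## Model overview

The package treats miRNA maturation as two sequential site-selection
problems on a folded hairpin. Both cleavage sites are represented as
integer boundaries on the 5′ arm (0-based: a cut before index `p`); the
paired strand's cut follows deterministically from the 2-nt 3′ overhang
that RNase III enzymes leave:

* **Drosha:** the pre-miRNA is `sequence[d : partner(d) + 3]` — its 3′ end
  overhangs the cut's pairing partner by 2 nt.
* **Dicer:** for a cut `c` after the 5p mature's 3′ end, the 3p mature
  starts at `partner(c − 3)` — the 5p 3′ end overhangs the 3p 5′ end by
  2 nt.

When the relevant endpoint is unpaired, its partner is extrapolated from
the nearest paired position toward the terminal loop, corrected by the
scan distance (the local region is treated as if perfectly stacked). This
one consistent algebra is used for candidate projection, truth derivation
from mature annotations (5p annotations take precedence; 3p-only
annotations are inverted through the same formulas) and mature assembly,
and is closed under round-trip: planting a site, writing annotations and
re-deriving recovers the site exactly.

## Secondary structure and energies

Structures are minimum-free-energy folds from ViennaRNA (Turner 2004
nearest-neighbor parameters). **Dangling-end and terminal-mismatch
exterior contributions are disabled** (`dangles = 0`). This is a deliberate
trade: it makes the stem's loop-energy decomposition *exactly* additive,
so the stack-face profile conserves energy against the evaluator — the
invariant the test suite checks — at the cost of slightly different MFE
structures than default folding would give. Stored dot-bracket structures
(e.g. designed synthetic structures) are accepted everywhere a fold would
otherwise be computed.

The stem of interest is selected by walking outward from a hairpin loop
through stacks, bulges and internal loops until a multiloop junction or
the exterior loop. With an anchor (annotated mature span, else the window
midpoint — windows are assumed extracted centered on the hairpin) the
covering stem wins; otherwise the stem with most pairs.

**Stack faces.** Each element of the stem path maps onto faces indexed by
5′-arm boundaries: a stack contributes one face with its stacking ΔG; a
loop with `u5` unpaired 5′-arm nucleotides contributes `u5 + 1` faces
carrying equal shares of the loop's total ΔG (initiation + asymmetry +
closure). Equal splitting is the only allocation that conserves energy;
indexing by 5′-arm steps keeps faces aligned with the cut-site coordinate
system. The alternative `max(u5, u3) + 1` split is available as
`profile.loop_split = maxarm` for pattern exploration but is not the
default, because its surplus faces have no unique 5′-arm boundary. Faces
requested beyond the structured stem (in the ssRNA flank) are reported as
0.0 kcal/mol and flagged as padding — neutral on a scale where stacks are
negative and loops positive.

## Features and ranking

* Drosha candidates: every 5′-arm boundary whose projected pre-miRNA is
  50–80 nt and that leaves room for at least a 16-nt mature on the stem.
  Features: faces 0..19 downstream of the cut plus the pre-miRNA length
  (21 total).
* Dicer candidates: mature lengths 16–25 whose cut stays on the stem of
  the **refolded** pre-miRNA (`dicer.refold = false` inherits the
  pri-miRNA pairing instead; refolding is the default because the excised
  chain folds on its own after nuclear export). Features (42): the 6×6
  internal-loop grid over the mature region as *counts* of loops with an
  exact `u5 × u3` signature — a count grid is informative where a summed-
  size grid would conflate one large loop with several small ones — plus
  per-arm bulge counts and bulged-nucleotide totals, the 1-based position
  of the first paired nucleotide, and the mature length. Internal loops
  with either side over 6 nt put the record outside the regular domain:
  such records are excluded from training and evaluation, and at
  prediction time receive a flagged best-effort prediction with clipped
  counts.

Ranking uses a bagged random forest (scikit-learn) with random
feature-subset splits of size `floor(log2 d) + 1`. The score of a
candidate is the **fraction of trees voting "true site"** — with one tree,
scores are exactly 0 or 1. Per hairpin the argmax wins; ties break to the
smaller position. Defaults: 100 trees (vote fractions in steps of 0.01
give a stable argmax; configurable), no class reweighting despite the
~1:15 positive:negative candidate imbalance (a `train.balance` switch
enables inverse-frequency weights), and candidates within ±1 nt of the
truth are excluded from both training classes (`train.margin`), since
near-misses are ambiguous labels.

## Synthetic data: what it emulates and what it does not

The generator builds hairpins from explicit stem plans: a 14–20 bp lower
stem below the planted Drosha cut, an upper stem sized so the pre-miRNA is
50–80 nt, a 6–12 nt terminal loop, random 1–3 nt bulges/internal loops at
a 6% per-step rate, and 30-nt A/C flanks (A and C cannot pair with each
other, keeping the flanks single-stranded). Truth sites obey the overhang
algebra by construction and are only planted at cleanly paired boundaries.

`signal_strength s` interpolates between a null and a learnable benchmark:

* with probability `s`, the Drosha cut sits at the constructed position
  and lower-stem pairs follow (each with probability `s`) a template with
  a GC (strong-stack) trough 10–14 faces downstream of the cut and weak
  AU stacks at 15–20 — a vertebrate-like energy pattern; the Dicer cut is
  bracketed by small 3′-arm bulge markers (which do not shift 5′-arm
  coordinates) and its mature length is drawn from a 22-nt-peaked
  distribution;
* otherwise, truth is placed **uniformly over the record's valid candidate
  sites** and composition is random. At `s = 0` the truth is therefore
  exchangeable with the other candidates, which gives the null benchmarks
  an exact analytic chance rate.

Planting acts on sequence composition only; energies are always computed
from the sequence by the evaluator. What passing the synthetic benchmarks
shows: the full chain — folding, decomposition, feature extraction,
ranking, overhang algebra — recovers planted signal well above chance and
degrades to exactly chance when no signal exists. What it does not show:
performance on real hairpins, whose composition statistics, annotation
noise and family structure the generator does not emulate (no k-mer
realism, no conservation, no expression bias).

## Benchmarks and problem sizes

The standard benchmark (used by the test suite) trains on 300 planted
hairpins at `s = 0.8` and evaluates 100 held-out hairpins, folding every
sequence from scratch. Recovery is compared against the analytic
random-argmax baseline `mean(1/|candidates|)` (~1/15 for Drosha, 1/10 for
Dicer): within-2-nt accuracy must exceed three times that baseline.
Typical runs land at ~0.82 (Drosha) and ~0.68 (Dicer) within 2 nt. Note
that because consecutive Drosha boundaries change pre-miRNA length by
~2 nt, only ~15 boundaries fit the 50–80 nt window, so the *within-2-nt
chance rate* (~5/15) is itself high; multiples of it are not a usable
recovery criterion, which is why the exact-hit chance is the baseline.
The zero-signal null uses a binomial test at α = 0.01 against the exact
chance rate implied by uniform truth placement. Other suite sizes —
100 hairpins for energy conservation, 200 for enumeration oracles, 1000
draws for truth round-trips — were chosen to exercise the combinatorics
densely while keeping the whole suite under a minute of structure work.

## Numerical choices and edge cases

* Energies are the evaluator's integer centi-kcal values divided by 100;
  conservation is asserted to 0.5 kcal/mol (the residual is the exterior
  terminal-pair penalty difference between full and stripped structures),
  loop-face splits to 1e-9.
* Population SD (divisor *n*) is used for deviation spread, matching the
  cross-validation convention of the tool comparisons this metric mirrors.
* The redundancy filter aligns globally (match 1, mismatch 0, gap −1) and
  drops later records over 90% identity (matches / alignment columns);
  it is greedy, order-deterministic and idempotent.
* Decoy-hairpin admission ("no more than 18 stem pairs, MFE ≤ −15
  kcal/mol") is implemented literally; the pairing criterion direction is
  switchable (`stem_pairs_at_most=False`) because miRNA-like decoys are
  sometimes screened for *at least* that many pairs, and the literal
  reading may be a translation slip in the original description.
* Degenerate inputs: unfoldable sequences, hairpins with no 50–80 nt
  candidate, refolds without a stem and matures ending in the terminal
  loop are reported as flagged irregular results, not exceptions, at
  prediction time; training skips them and counts them.
* Determinism: a fixed config and seed reproduce byte-identical TSV
  output; model files embed a schema version and refuse to load on
  mismatch.

## Known limitations

* Single-stem model: multiloop junctions truncate the walk; hairpins whose
  mature region spans a multiloop are out of domain.
* No coaxial stacking or pseudoknots; suboptimal/ensemble structure is
  ignored.
* The Dicer stage models secondary structure only; 3D ruler effects are
  summarized indirectly by the length feature.
* Absolute vote-fraction scores depend on forest hyperparameters; only
  their ordering is meaningful.
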