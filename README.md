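# gaitprint

Gait-based person identification and its explanation: which parts of a
runner's movement pattern are *unique* to the individual, and which are
*generic* to the cohort?

`gaitprint` implements the full analysis as a tested, reusable Python
library:

1. **Synthetic cohorts** — a seeded generator of full-body running
   kinematics (18 joints x 3 planes at 240 Hz, plus vertical foot/toe
   positions with ground-contact plateaus) in which every participant
   shares one generic waveform and differs only through *planted*
   signature deviations in known phase windows — so every downstream claim
   can be checked against ground truth.
2. **Gait events and step cycles** — touch-down/take-off detection from
   vertical foot and toe positions (first/last sample below a threshold
   2 cm above the window-local minimum), step-cycle segmentation between
   consecutive touchdowns of opposite feet, time normalization to a fixed
   grid, trunk mirroring and standing/swinging relabeling. A canonical
   cycle is `100 x 18 x 3 = 5400` variables.
3. **Screening and scaling** — per-participant outlier removal with local
   outlier probabilities (LoOP) on 3-PC loadings, then per-cycle scaling
   to [-1, 1], assembled into one cycles-by-variables data matrix.
4. **Identification** — a three-layer network (`n` inputs, `2n` tanh
   hidden nodes, one output per participant) trained on a handful of
   cycles per runner from the training trials and evaluated on every cycle
   of a held-out trial; accuracy per participant is
   `n_correct / n_total * 100`.
5. **Explanation** — layer-wise relevance propagation (epsilon rule)
   redistributes each correct classification back to the input variables;
   patterns are smoothed (0.25/0.50/0.25 kernel, twice), aggregated
   participant-wise (mean, rectify, max-normalize), averaged and ranked.
6. **Unique vs generic** — held-out cycles restricted to the k most or
   least relevant variables are projected onto their first three principal
   axes; each runner's point cloud is bounded by an alpha shape and the
   pairwise intersection volume (Monte-Carlo, as % of the reference
   runner's volume) is traced as k grows in steps of five. Low overlap =
   unique characteristics, high overlap = generic ones. The extreme 10%
   of variables are profiled by movement plane, cycle time and joint
   group.

See `docs/methods.md` for the models, defaults and numerical conventions,
and `examples/` for one short narrative script per capability.

## Worked example

A 6-runner cohort, 15 s per trial, at the reduced 25-point cycle grid
(`examples/03_identification.py`):

```
network: 1350 -> 2700 (tanh) -> 6 nodes; training on 60 cycles (10 per runner)
trained for 436 epochs (early stop: True), final loss 0.0469
participant  n_correct  n_total  accuracy
        P01         39       39     100.0
        P02         35       35     100.0
        P03         37       37     100.0
        P04         37       37     100.0
        P05         37       37     100.0
        P06         39       39     100.0
overall held-out accuracy: 100.00% (224 TR cycles)
```

Every held-out step cycle is assigned to the correct runner. Ranking the
variables by aggregated relevance and comparing runners' point clouds in
the resulting principal subspaces (`examples/05_subspace_overlap.py`):

```
mean pairwise overlap (% of the reference runner's volume):
 subset size   most relevant  least relevant
          10            0.0%           48.6%
         310            0.0%           48.1%
         610            0.0%           46.0%
         910            0.0%           20.4%
```

Runners are nearly non-overlapping in subspaces built from the most
relevant (unique) variables, while the least relevant (generic) variables
leave their movement patterns substantially intermingled — and growing the
subspace shrinks the overlap in both directions. On synthetic data the
top-ranked variables can be checked against the generator:
`examples/04_relevance_ranking.py` reports how much of the top 10% falls
inside the planted-signature mask.

## Command line

The pipeline is also runnable as a shell tool, one subcommand per stage
over persisted artifacts:

```bash
gaitprint all --seed 3 --scale reduced --outdir run/
gaitprint simulate --outdir run/   # then: segment, preprocess, train,
                                   # relevance, overlap, profile
```

Each run writes a manifest with derived seeds, cycle counts, accuracies
and a SHA-256 checksum per artifact; identical configurations reproduce
identical numbers.

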