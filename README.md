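# patchforage

Quantitative analysis of effort-discounting-like foraging behaviour in
*Caenorhabditis elegans*.

When a worm chooses between a patch of normal bacteria and a patch of
elongated (harder-to-eat) bacteria, it devalues the effortful option. This
package implements the analysis pipeline for that behaviour, for
behavioural neuroscientists and quantitative ethologists working with
patch-foraging assays:

* **Economic discounting model.** At an indifference point the two options
  have equal perceived value, `V(E) = d(E)·V₀` with discount factor
  `0 ≤ d(E) ≤ 1`. With perceived value linear in bacterial optical density
  (OD), one measured indifference pair fixes `d = V(E)/V₀` and predicts every
  other indifference pair at the same effort level (`EffortDiscountModel`).
* **Three-state patch-leaving kinetics.** Each video frame is classified as
  F (*On Food*: head and tail both in contact with the patch), B (*At
  Border*: exactly one in contact) or O (*Off Food*: neither). The linear
  chain F ↔ B ↔ O has four rate constants `k_XY = N_XY / T_X` (transitions
  over time in the origin state) and state probabilities
  `P_X = T_X / ΣT` (`PatchKineticsModel` / `PatchKineticsResults`).
* **Preference statistics.** Per-plate two-choice preference index
  `I = (n_N − n_L)/(n_N + n_L)`, one-sample *t* tests with 95% CIs, one-way
  ANOVA with `η² = SS_between/SS_total`, Welch corrections, rank-biserial
  `r = 2U/(n₁n₂) − 1`, the isometric log-ratio transform for the
  compositional state probabilities, and the extreme-outlier box-plot rule.
* **Electropharyngeogram (EPG) pump detection.** Band-pass filtering,
  MAD-relative thresholding and refractory peak picking recover individual
  pharyngeal pumps and cohort mean pumping frequency.
* **Synthetic data generators** for all three data types (CTMC-rendered
  tracks in a circular arena, binomial T-maze plate counts, jittered-regular
  pump trains in noise), so the whole pipeline is testable end to end
  without recordings.

## Worked example

```python
import patchforage as pf

# --- economic model from the measured indifference point -------------------
model = pf.EffortDiscountModel.from_indifference(v_indiff=1.0, v0=1.5)
print(model.report())

# --- simulate a patch-leaving cohort and fit the kinetic model -------------
tracks = pf.simulate_tracks(10, seed=1)          # 10 worms, 15 min at 2 fps
res = pf.PatchKineticsModel(tracks).fit()
print(res.summary())
```

Output:

```
Effort-discounting model
  effort: cephalexin-450uM-2h
  discount factor d = 0.666667
  predicted indifference points (elongated OD -> normal OD):
    OD 0.75 -> OD 0.5
    OD 1.5 -> OD 1
    OD 3 -> OD 2
Three-state patch-leaving kinetics
==================================
worms: 10    total observation: 9000 s

Pooled (sum N / sum T):
  P_F=0.9085  P_B=0.0694  P_O=0.0221
  k_FB=0.1761  k_BO=0.6723  k_OB=2.1159  k_BF=2.2089  (per min)

Per-worm means (SD):
  P_F         0.9085 (0.0617)
  P_B         0.0694 (0.0552)
  P_O         0.0221 (0.0305)
  k_FB        0.1802 (0.1065)
  k_BO        0.8271 (0.9315)
  k_OB        3.5357 (3.3095)
  k_BF        2.6322 (1.2776)
  speed_on    0.0500 (0.0000)
  speed_off   0.1500 (0.0000)
```

The discount factor of 2/3 comes from the indifference pair (normal OD 1.0
vs elongated OD 1.5); the model then predicts that *any* 2:3 OD ratio is an
indifference point, e.g. OD 2 vs OD 3. In the simulated cohort the pooled
rate constants approach the generator's defaults (k_FB = 0.2, k_BO = 0.5,
k_OB = 1.5, k_BF = 2.0 per min; ten worms leave visible sampling error in
the rarely visited O state) and reproduce the qualitative signature of
efficient foraging: entry rates exceed exit rates (k_BF > k_FB,
k_OB > k_BO), so most time is spent on food (P_F ≈ 0.91 here, stationary
value 0.88).

A command-line interface mirrors the library:

```sh
patchforage simulate tracks --out tracks/ --n 10 --seed 1
patchforage kinetics estimate --tracks tracks/ --patch tracks/patch.csv --out est.csv
patchforage discount predict --v0 3 --d 0.6667
```

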