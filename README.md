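# alinfo — information preservation in the *Drosophila* antennal lobe

`alinfo` is a computational-neuroscience package for asking how much
information about odor identity survives the first synaptic relay of the fly
olfactory system, and which circuit configuration preserves the most.  It is
aimed at researchers modelling sensory coding in glomerular circuits
(olfactory bulb / antennal lobe style architectures) who want a compact,
fully reproducible pipeline from a stochastic spiking circuit model to
information-theoretic readouts.

## The model and the question

Odors are encoded by olfactory receptor neurons (ORNs); all ORNs of one
receptor type converge on one glomerulus, where they drive projection
neurons (PNs).  Local neurons (LNs) pool activity across all glomeruli and
feed it back laterally to every PN.  The package simulates this circuit with
Poisson spiking neurons and exponential synapses (time constant τ = 2 ms):

* each glomerulus's feed-forward drive is the per-ORN-averaged filtered
  spike train of its ~40 ORNs, so a receptor firing at rate *r* contributes
  a mean drive *r·τ·w_ff*;
* LNs fire at a rate proportional to total ORN activity and feed every PN a
  lateral input scaled by a signed strength *w_lat* (negative = inhibition —
  adaptive gain control, because it grows with total stimulus strength);
* the PN firing rate is a threshold–power–saturation function of its total
  input: zero below θ, *r_max* = 200 Hz above *x_max*, and
  *r_max·((x−θ)/(x_max−θ))^β* in between.  β < 1 (concave) preferentially
  amplifies weak inputs, β > 1 (convex) suppresses them.

The response to one stimulus presentation is the vector of PN spike counts
in a 10 ms bin (capped at 5).  Over an ensemble of S odors presented with
equal probability, the package computes the mutual information

    I = H − H_noise,
    H        = −Σ_r P(r) log₂ P(r)
    H_noise  = Σ_s P(s) [−Σ_r P(r|s) log₂ P(r|s)]

either exactly by enumerating all (cap+1)^N response patterns from plug-in
conditional distributions (tractable for 8 glomeruli × 1 PN), or as a lower
bound via decoding: a one-against-one linear-SVM classifier predicts the
odor and I(S; Ŝ) is read off the confusion matrix — never larger than the
true MI, by the data-processing inequality.

Sweeping the two free parameters (β, w_lat) maps an information landscape
with two maxima: **peak i** (concave transformation + lateral inhibition,
the configuration observed in the fly) and **peak e** (convex + lateral
excitation), plus **point n**, the best circuit without any lateral input.
Entropy decomposition and per-odor-pair discrimination analyses dissect why
peak i wins: concavity raises response entropy faster than noise entropy,
and adaptive inhibition cuts noise while pulling saturated responses apart.

Measured ORN rate matrices can be loaded from TSV/CSV; a synthetic
generator reproduces their statistical signature (most responses weak, a
minority strong, a few hundred Hz ceiling) for self-contained experiments.

## Worked example

```python
from alinfo import (CircuitParams, synthesize_orn_matrix, run_ensemble,
                    estimate_conditional, mutual_information_exact,
                    decoded_mi_experiment, sweep_mi, find_peaks)

matrix = synthesize_orn_matrix(8, 20, seed=11)      # 8 glomeruli, 20 odors
params = CircuitParams(beta=0.5, w_lat=-1.0)        # concave + inhibition

table = run_ensemble(matrix, params, n_trials=400, seed=3)
info = mutual_information_exact(estimate_conditional(table))
print(f"H = {info.entropy:.3f} bits, Hn = {info.noise_entropy:.3f} bits, "
      f"I = {info.mutual_information:.3f} bits")

grid = sweep_mi(matrix, CircuitParams(), seed=3)    # default (beta, w) grids
print(find_peaks(grid))
```

prints

```
H = 8.943 bits, Hn = 7.655 bits, I = 1.288 bits
PeakReport(peak_i=(0.3, -1.0, 1.33307912313985), peak_e=(1.4, 1.0, 1.0020764898147876), point_n=(0.7, 1.2859805674325369))
```

i.e. this 20-odor ensemble carries 1.29 bits at the concave-inhibitory
operating point, and the grid search puts the global information maximum in
the concave/inhibitory quadrant (peak i), above both the
convex/excitatory region's best (peak e) and the best lateral-free circuit
(point n).

The same analyses are available from the shell:

```bash
alinfo synth --n-receptors 8 --n-odors 20 --seed 11 -o matrix.tsv
alinfo mi-exact --odors matrix.tsv --trials 400 --seed 3 -o mi.json
alinfo sweep --odors matrix.tsv --seed 3 -o grid.csv --peaks peaks.json
alinfo pairs --odors matrix.tsv --w-inhib -1.0 --seed 3 -o pairs.csv
```

## Package layout

| module | contents |
| --- | --- |
| `alinfo.odors` | ORN rate matrices: loading, synthesis, glomerulus subsetting |
| `alinfo.circuit` | the stochastic ORN→(LN)→PN simulator |
| `alinfo.info_exact` | plug-in entropy / noise-entropy / MI by enumeration |
| `alinfo.info_decoded` | one-vs-one linear-SVM decoding and confusion-matrix MI |
| `alinfo.sweep` | (β, w_lat) landscapes, peak finding, transform summaries, threshold experiments |
| `alinfo.pairs` | pairwise discrimination metrics, category tables, PCA views |
| `alinfo.cli` | `alinfo` command-line interface |

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
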