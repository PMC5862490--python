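# flimphasor

Phasor (polar-plot) analysis of NADH fluorescence-lifetime imaging (FLIM)
data acquired by time-correlated single photon counting (TCSPC), built for
studies that probe cerebral metabolism: pharmacological manipulations of
glycolysis or mitochondrial pathways (TCA cycle, electron transport chain,
OXPHOS uncoupling) change the balance of free versus enzyme-bound NADH,
which shifts both the fluorescence decay and the total NADH intensity. The
package takes H×W×T photon-count stacks from paired baseline/treated
acquisitions and reduces them to per-measurement features, tests which
conditions separate from baseline, and classifies metabolic disruptions —
including a synthetic TCSPC study generator so the whole chain is testable
without access to in vivo measurements.

## The model

For a decay histogram $I(t)$ (256 bins over a 12.5 ns window at an 80 MHz
repetition rate), the phasor at harmonic $k$ of the repetition frequency
$f$, with $\omega = k\,2\pi f$, is the intensity-normalized Fourier
component

$$g(\omega) = \frac{\sum_i I(t_i)\cos\omega t_i}{\sum_i I(t_i)}, \qquad
  s(\omega) = \frac{\sum_i I(t_i)\sin\omega t_i}{\sum_i I(t_i)},$$

summed over bin centers $t_i$ across the entire decay. Single-exponential
decays with lifetime $\tau$ fall on the *universal circle*
$(g-\tfrac12)^2 + s^2 = \tfrac14$, at
$g = 1/(1+(\omega\tau)^2)$, $s = \omega\tau/(1+(\omega\tau)^2)$;
multi-exponential mixtures fall inside it at the fractional-fluorescence-
weighted vector sum of their components. Phasors are referenced against a
measured free-NADH solution standard of known lifetime (a single complex
phase/modulation correction per harmonic), which absorbs instrument-response
delay and early-bin truncation by the timing electronics.

Downstream, each imaging session becomes one feature row
$(g, s, \Delta I)$ — the pixel-averaged phasor over the vessel-masked field
of view plus the relative intensity change from baseline. Condition clusters
are summarized by standard deviational ellipses, tested against baseline
with the two-sample Hotelling $T^2$ statistic, and classified (LDA, KNN,
naive Bayes) with stratified K-fold cross-validation.

## Worked example

```python
import numpy as np
from flimphasor import (AcquisitionMeta, LifetimeMixture, RunConfig,
                        generate_decay, pixel_phasor, run_full_analysis)

meta = AcquisitionMeta()            # 80 MHz, 256 bins, 12.5 ns
mix = LifetimeMixture((0.3, 0.8, 2.0, 4.0), (0.12, 0.18, 0.45, 0.25))
decay = generate_decay(mix, 1e6, meta)          # noise-free expected decay
p = pixel_phasor(decay, harmonic=1)
print(f"(g, s) = ({p.g:.4f}, {p.s:.4f})")
# (g, s) = (0.5456, 0.4048)   <- inside the universal circle: mixed decay

res = run_full_analysis(RunConfig(seed=1))
print(res.separability[["condition", "harmonic", "t2", "p_value"]])
```

The separability report for the default synthetic study (5 conditions ×
9 paired measurements each) prints:

```
            condition  harmonic        t2  p_value  significant
       etc_inhibition         1 1787.2872   0.0000         True
       etc_inhibition         2 1675.3494   0.0000         True
glycolysis_inhibition         1    1.5517   0.4995        False
glycolysis_inhibition         2    1.7177   0.4654        False
    oxphos_uncoupling         1  195.3293   0.0000         True
    oxphos_uncoupling         2  201.8354   0.0000         True
       tca_inhibition         1  500.3518   0.0000         True
       tca_inhibition         2  548.1760   0.0000         True
```

Every mitochondrial manipulation separates cleanly from baseline at both
harmonics while glycolysis inhibition does not — the qualitative pattern
these pipelines are designed to resolve. The three classifiers trained on
(g, s, ΔI) all reach cross-validation accuracy 1.0 on this synthetic study
and assign ≥ 89 % of held-out seizure-like measurements to the ETC class,
whose preset they mimic.

The same pipeline is available from a shell:

```sh
flimphasor run --seed 1 --out results/run1
flimphasor simulate --preset etc_inhibition --out scenes/
flimphasor classify results/run1/measurements.csv --algo lda --harmonic 1
```

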