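# chronospeckle

Analysis toolkit for **~12-hour ultradian rhythms in nuclear-speckle
biology**: damped-sinusoid rhythm detection by the eigenvalue/pencil
(matrix-pencil) method, kinetic inversion of paired pre-mRNA/mature-mRNA
time courses into a time-varying mRNA processing rate, intron/exon read
quantification, gene-body coverage integration, speckle sphericity
morphometry, and FRAP recovery fitting — together with a synthetic-data
generator that provides exact ground truth for every stage, so the whole
pipeline is testable without any external dataset.

It is written for chronobiologists and RNA/condensate biologists who have
temporal data — expression matrices sampled every 2 h over 48 h,
time-lapse microscopy of GFP-tagged speckle markers, FRAP traces — and
want to ask: *is there a 12-hour rhythm here, how strong is it, and when
does it peak?*

## The models

**Rhythm detection.** A uniformly sampled series is decomposed into
exponentially damped cosines

```
x_k = Σ_j  A_j · d_j^k · cos(2π t_k / T_j + φ_j)
```

by a matrix-pencil eigenproblem on the signal's Hankel matrix. Unlike a
periodogram, this resolves superposed 24-h and 12-h components from a
48-h record and returns a per-component damping factor `d` (per sampling
interval; `d ≈ 1` means sustained). The dominant oscillatory component is
classified **circadian** (period 21–25 h, decay 0.8–1.2), **ultradian12**
(period 10.5–13.5 h, decay 0.8–1.2) or **other**; a permutation scheme
(common time-shuffling of all series, B ≥ 100 rounds) estimates the FDR
of a call set.

**Processing-rate inversion.** Pre-mRNA p(t) converts to mature mRNA m(t)
at a time-varying processing rate k_p(t), and mature mRNA decays at a
constant k_d (default 0.1 h⁻¹ when no measured rate is available):

```
dm/dt = k_p(t)·p(t) − k_d·m(t)      ⇒      k_p(t) = (dm/dt + k_d·m) / p
```

Sparse 2-h courses are densified by spline regression to a 0.25-h grid
and differentiated by the forward difference `[m(t+0.25) − m(t)]/0.25`.

**Morphometry.** Speckle shape is summarized by the sphericity
`2·sqrt(π·area)/perimeter` (1 for a circle, → 0 for a line), aggregated
per cell as the area-weighted mean. Round "nucleation" droplets score
high; connected "spinodal" networks score low, making the per-cell value
a morphology readout that can be tracked over time and fed back into the
rhythm detector.

**FRAP.** Three-channel traces are normalized as
`(bleached − background)/(reference − background)`, fit by single- and
double-exponential recovery models, the larger R² wins (ties go to the
simpler model), and the recovery half-life t₁/₂ is reported as a
fluidity proxy.

## Worked example

Simulate six genes carrying a 12-h processing-rate rhythm
(k_p = 0.2·(1 + 0.5·cos), random phases, 2-h sampling for 48 h), then
invert the observed pre/mature matrices back into k_p:

```sh
chronospeckle simulate --out demo --seed 7 --n-genes 6
chronospeckle kp --pre demo/pre.csv --mature demo/mature.csv --out demo/kp.tsv
```

```
gene_id  kp_mean     kp12_amplitude_log2  acrophase_h  label
g0000    0.1989622   0.76222958           8.3054896    ultradian12
g0001    0.20379619  0.74248384           5.2248135    ultradian12
g0002    0.19609549  0.75729634           10.782693    ultradian12
...
```

Every gene is recovered as `ultradian12`. The mean rate matches the
simulated baseline 0.2 h⁻¹; the log2 amplitude ≈ 0.76 is the analytic
first harmonic of log2(1 + 0.5·cos) (≈ 0.77); and `acrophase_h` is the
clock time (hours, mod 12) at which each gene's processing rate peaks —
it varies because each simulated gene was given a random phase.

Fitting a synthetic FRAP trace (k = ln2/10 s⁻¹, i.e. a 10-s half-life):

```
>>> fit = fit_recovery(normalize_frap(trace))
single fit, R2=1.00000, t1/2=10.000 s
```

## Layout

| module | contents |
|---|---|
| `chronospeckle.rhythm` | matrix pencil, classification windows, periodogram, permutation FDR, acrophase |
| `chronospeckle.kinetics` | spline densification, forward difference, k_p inversion |
| `chronospeckle.genomic` | intron/exon counting, FPKM, gene-body and metagene coverage |
| `chronospeckle.morphometry` | speckle segmentation, sphericity, temporal series |
| `chronospeckle.frap` | trace normalization, exponential fits, half-life |
| `chronospeckle.simulate` | ground-truth generators for every stage |
| `chronospeckle.pipeline` / `.cli` | reproducible runs, `chronospeckle` command |

See `docs/methods.md` for the modeling choices, parameter defaults, and
known limitations.
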