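# popcode — optimal linear population coding for sensory systems

`popcode` answers a classic question in early sensory neuroscience: given a
degraded input and a limited population of noisy neurons, what is the best
linear code, and what do its receptive fields look like?  It implements the
minimum-mean-squared-error solution for a linear gaussian coding chain and
the machinery to turn that (highly non-unique) solution into structured
receptive-field populations — including the center-surround fields of
retinal ganglion cells, which emerge under a spatial-locality cost.

The intended users are computational neuroscientists and signal-processing
researchers studying efficient coding, retinal modeling, or noisy linear
compression.

## The model

An original signal **s** ∈ ℝᴺ (zero mean, covariance Σₛ = E Λ Eᵀ) is blurred
and corrupted before it reaches the encoder, and the code itself is noisy:

    x = A s + n,        n ~ 𝒩(0, σₙ² I)      (observed signal)
    r = W x + δ,        δ ~ 𝒩(0, σ_δ² I)     (neural representation, M units)
    ŝ = G r                                   (linear readout)

`G` is the Wiener filter, and `W` is chosen to minimize E‖s − ŝ‖² subject to
a response-power budget tr(WΣₓWᵀ) ≤ P = M·σ_δ²·SNR_neural.  The optimum
factors as **W = V Λ̃ Eᵀ**: a unique per-component gain profile Λ̃ obtained by
*water-filling* the budget over spectral components — component *i* is worth
at most sᵢ = λᵢ²aᵢ²/(aᵢ²λᵢ+σₙ²) of error reduction and receives power
pᵢ = max(0, √(sᵢσ_δ²/μ) − σ_δ²) — times an arbitrary M×M orthogonal matrix
V.  The expected error has the closed form

    MSE = Σᵢ [ λᵢ − sᵢ pᵢ / (pᵢ + σ_δ²) ].

The classical redundancy-reduction baseline (whitening, W(AΣₛAᵀ)Wᵀ = c²I) is
provided for comparison; the optimal code always reconstructs at least as
well, reduces to *half-whitening* when sensory noise vanishes, and truncates
high frequencies once their blurred signal falls below the noise floor.

Because the MSE is invariant to V, receptive-field *shape* is decided by
resource costs: L¹ weight sparsity, generalized-gaussian response sparsity,
or spatial locality (distance-weighted L² norm of squared weights).
`popcode.shaping` resolves V by projected-gradient steps with an
orthogonal-Procrustes projection back onto the optimal-MSE manifold (so the
total power constraint holds exactly and the error never degrades), or by a
one-shot projection of a gaussian-bump / identity target.

## Worked example

```bash
python examples/01_optimal_vs_whitening.py
```

prints, for the 100-component 1/f² signal with gaussian blur and 10 dB
neural SNR:

```
 sensory SNR    M  optimal %  whitening %  limit %
       -10dB   10       35.1         57.7     32.9
       -10dB  100       33.2        100.0     32.9
         0dB   10       15.8         23.8     11.3
         0dB  100       11.8        100.0     11.3
        10dB   10       10.8         15.1      3.7
        10dB  100        4.6         99.9      3.7
        20dB   10       10.1         14.0      1.4
        20dB  100        2.4         99.4      1.4
```

Each entry is the expected reconstruction error as a percent of signal
variance.  The optimal code dominates everywhere; whitening with a full
population wastes nearly all its capacity at low SNR (it amplifies exactly
the noise-dominated frequencies), while the undercomplete case (M = 10)
rescues it by accident — its truncation mimics the optimal cutoff.  The
`limit` column is the infinite-population bound set by blur and sensory
noise alone.

The other examples show the spectral mechanics (`02`), center-surround
emergence under the locality cost (`03`), the two-pixel repetitive code
(`04`), and light adaptation at fovea vs periphery cell ratios (`05`).

A thin CLI wraps the same library:

```bash
popcode solve --grid 15 15 --ratio 1 --sensory-snr 10
popcode shape --grid 15 15 --ratio 1 --constraint locality --gamma 0.1
popcode report --grid 15 15 --population-sizes 1,4,16,64,225
```

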