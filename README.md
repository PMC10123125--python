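# dnabow

Tools for analyzing DNA hybridization and dehybridization kinetics under
weak tension (2–6 pN), as measured with a *DNA bow*: a construct in which
a bent dsDNA arc (74–252 bp) exerts entropic tension on a short ssDNA
"bowstring" carrying a probe-binding target.  Probe binding and unbinding
are read out by two-state smFRET, and the force dependence of the rates
reports on the extension of the nucleated-duplex transition state.

The package is aimed at single-molecule biophysicists who want to
(i) calibrate the tension a bent arc exerts, (ii) turn donor/acceptor
intensity trajectories into rate constants, (iii) fit force-dependent
rate laws built on force–extension relations (FERs), and (iv) construct
umbrella-reweighted free-energy landscapes of duplex melting.  A seeded
synthetic-data module generates every input class, so the full pipeline
is testable without any experimental data.

## The model

The force dependence of the binding (`on`) and unbinding (`off`) rate
constants is modeled along a one-dimensional extension coordinate,

```
k_a(f) = k_a(0) · exp( ∫₀^f Δx‡(f′) df′ / k_BT ),
```

where Δx‡(f) = x‡(f) − x_u(f) for binding and x‡(f) − x_b(f) for
unbinding: the extension of the transition state (a duplex nucleated at a
single base pair) relative to the unbound ssDNA or bound duplex state.
With linear per-nucleotide FERs, x = n(f/κ + x₀), the integral closes to

```
k_on(f)  ≈ k_on(0) · exp[ (n/k_BT){ (1/κ‡ − 1/κ_u) f²/2 + (x₀‡ − x₀ᵤ) f } ]
k_off(f) ≈ k_off(0) · exp[ (n/k_BT){ (1/κ‡) f²/2 + (x₀‡ − x₀_b) f } ]
```

The arc tension is obtained from the worm-like-chain end-to-end distance
distribution p(x) via `f(x₀) = −k_BT ∂log p/∂x|₀`, with p(x) evaluated
by an interpolation accurate from the flexible to the stiff regime, and
free-energy surfaces G(x, n_bp; f) = −k_BT log p_eq + C are built from
umbrella-biased samples by dividing out the per-stratum weight W(n_bp).

## Worked example

Calibrate the tension of the smallest and largest bows (self-consistent
worm-like-chain arc loaded by the ssDNA bowstring):

```
$ bowkit calibrate-force --arc-bp 74 --self-consistent
arc 74 bp (unbound): x* = 6.006 nm, f* = 5.846 pN
$ bowkit calibrate-force --arc-bp 210 --self-consistent
arc 210 bp (unbound): x* = 4.183 nm, f* = 2.114 pN
```

The 74 bp arc pushes its ends apart with ≈5.8 pN while the 210 bp arc
gives ≈2.1 pN — the bow series spans the weak-tension window.  Next,
simulate a rate-versus-force table from the closed-form laws (zero-force
rates k_on(0) = 10⁷ M⁻¹s⁻¹, k_off(0) = 0.2 s⁻¹, 5% log-normal noise) and
fit the six-parameter model jointly to k_on(f) and k_off(f):

```
$ bowkit simulate rates --out ex --seed 4
$ bowkit fit-rates ex/rates.csv --model linear
{
  "model": "linear",
  "params": {
    "a_ts": 25.2,      # transition-state stiffness, pN/nm
    "a_u": 3.59,       # unbound (ssDNA) stiffness, pN/nm
    "b_ts": 3.46,      # transition-state rest extension, nm
    "b_u": 1.97,       # unbound rest extension, nm
    "kon0": 1.04e7,    # zero-force binding rate, 1/M/s
    "koff0": 0.2045,   # zero-force unbinding rate, 1/s
    ...
  }
}
```

The fitted rest extensions satisfy b_ts > b_u: the transition state is
more extended than the unbound strand, which is why *both* rates increase
with weak tension.  The zero-force rates are recovered within a few
percent of the generating values.

Other entry points: `bowkit analyze-traces <dir>` (smFRET trace CSVs to
rates), `bowkit landscape samples.csv --bias bias.toml --force 4`
(umbrella reweighting to a free-energy surface), `bowkit simulate
traces|rates|landscape|wlc` and `bowkit run` (full pipeline with a
provenance log).

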