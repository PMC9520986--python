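# fractalknots

Monte-Carlo and analytical tools for the random-knotting statistics of
**fractal ring polymers** — closed Gaussian chains whose size scales as
R ~ N^(1/d_f) for a prescribed fractal dimension d_f. Such rings model,
among other things, chromatin (d_f between 2 and 3), ideal rings
(d_f = 2) and fractal globules (d_f = 3). The package answers two
questions for this model class:

1. How does the probability P0(N) that an N-bead ring is *unknotted*
   decay with chain length?
2. How does the resulting knotting length N0 — defined through
   P0(N) ∝ exp(−N/N0) — depend on d_f?

## What is inside

- **`beta_model`** — ring conformations with prescribed d_f sampled
  from Gaussian Fourier modes with eigenvalues
  λ_q = 4k sin^χ(πq/N), χ = 1 + 2/d_f (χ = 2 is the Rouse ring), plus
  exact structural expectations used as test oracles.
- **`knots3d`** — knot typing of closed 3D polygons via the knot
  determinant |Δ(−1)| (Alexander invariant at t = −1, exact integer
  arithmetic): KMT triangle-elision simplification, generic projection
  to a crossing diagram, Wirtinger crossing matrix. Determinants: 1 for
  the unknot, 3 for the trefoil, 5 for the figure-eight.
- **`planar2d`** — the 2D analogue, where a ring is "knotted" iff two
  non-adjacent segments intersect.
- **`knotstats`** — Wilson intervals for P0, weighted exponential fits
  for N0, the μ = ln N0 versus d_f curve, competing double-exponential /
  logarithmic fits with information-criterion comparison, and the exact
  thermodynamic estimator of d ln P0/dχ from classified samples.
- **`theory`** — the analytical apparatus: Flory exponent
  γ(d_f) = 1 + 4(1 + 1/d_f)/(d + 2), the two-regime mode-amplitude
  model, the coefficient functions f1/f2 of the ODE
  dμ/dd_f = f1 μ + f2, its closed-form double-exponential solution
  μ = c1 e^(c2 d_f) + c3, and the representative constants c2 = f1,
  c3 = −f2/f1.
- **`campaign` / `cli` / `io`** — seeded, byte-reproducible campaign
  orchestration, a `fractalknots` command line
  (`sample`, `classify`, `pcurve`, `fit`, `mucurve`, `theory`,
  `campaign`), and XYZ/CSV/JSON formats.

## Worked example

Measure P0(N) for ideal rings (d_f = 2), fit the knotting length, and
compare the μ(d_f) curve of a small campaign against theory:

```python
import numpy as np
from fractalknots.campaign import CampaignConfig, run_campaign

cfg = CampaignConfig(
    d=3,
    df_grid=(1.5, 1.8, 2.0, 2.5, 3.0, 4.0, 5.0),
    samples=1500,
    seed=11,
)
result = run_campaign(cfg)
print(result.fits_frame()[["d_f", "N0", "mu", "mu_stderr"]])
de = result.mu_fits["double_exponential"]
lg = result.mu_fits["logarithmic"]
print(f"double-exp: c2={de.c2:.3f} c3={de.c3:.3f} aicc={de.aicc:.1f}")
print(f"logarithmic aicc={lg.aicc:.1f}")
```

Output (a few minutes on one CPU):

```
   d_f           N0        mu  mu_stderr
0  1.5  1383.249577  7.232191   0.059536
1  1.8   484.915245  6.183974   0.035345
2  2.0   309.211836  5.734027   0.030279
3  2.5   142.192584  4.957182   0.026033
4  3.0    91.423208  4.515499   0.022900
5  4.0    62.838725  4.140572   0.022610
6  5.0    48.106594  3.873419   0.023897
double-exp: c2=-1.082 c3=3.860 aicc=33.4
logarithmic aicc=87.1
```

Reading the numbers: ideal rings knot on a scale of ~300 beads, and the
knotting length falls steeply — but *not* logarithmically — as the ring
becomes more compact. μ(d_f) is captured by the double-exponential form
(so N0 itself is doubly exponential in d_f, and the knotting
probability is a triple exponential), while the logarithmic form typical
of simple scaling arguments is strongly disfavoured by the information
criterion.

Single conformations work too:

```python
from fractalknots import build_spectrum, sample_ring, classify_knot

spectrum = build_spectrum(N=200, d_f=3.0, d=3)
ring = sample_ring(spectrum, np.random.default_rng(0))
call = classify_knot(ring, np.random.default_rng(1))
print(call.determinant, call.is_trivial)
```

or from the shell:

```sh
fractalknots sample -N 200 --d-f 3.0 -n 100 --seed 0 -o rings.xyz
fractalknots classify rings.xyz -o calls.csv
fractalknots theory -o theory.csv
```

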