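# plastideg

Quantitative analysis of marine biodegradation of bioplastics — from
gravimetric field measurements on the seafloor to the plastisphere
microbiome colonising the polymer surface.

Biodegradable polyesters (PHB, PHBH, PBSA, ...) deployed in seawater are
eaten from the surface by microbial depolymerases at a roughly constant
rate, so a handful of simple models carry the whole analysis. `plastideg`
implements them as a tested library with a thin CLI, for materials
scientists and microbial ecologists running (or simulating) seafloor
deployment campaigns:

* **Erosion kinetics** (`plastideg.kinetics`) — weight loss
  (Wi − Wf)/Wi × 100; the area-normalised biodegradation rate
  V = ΔW·10⁶/A/t in μg/cm²/day; OLS thinning rates from thickness series;
  the linear residual-weight model
  residual(%) = 100 − V·S·t·10⁻⁶/m × 100 and its inversion, the
  complete-degradation lifetime t* = m·10⁶/(V·S) of a thin-film article
  (default: a 18 × 42 cm, 15 μm, 3 g shopping bag, S = 3024 cm²); and an
  erosion-consistency ratio that flags perforation when mass loss outruns
  face thinning.
* **BOD biodegradability** (`plastideg.bod`) — theoretical oxygen demand
  ThOD = w/M · (4x + y − 2z)/4 · 32 for a CxHyOz monomer, blank-corrected
  biodegradability (BODs − BODb)/ThOD × 100, and plateau/t90 summaries of
  closed-bottle time series.
* **Community statistics** (`plastideg.community`) — RpsC (ribosomal
  protein S3) single-copy-marker profiles weighted by scaffold coverage ×
  protein length; pooled coverage-weighted amino-acid composition;
  the thermophily proxy T_opt(°C) = F_IVYWREL × 937 − 335; the redox proxy
  Z_C = (Z + 2(nO+nS) + 3nN − nH)/nC; Shannon and bias-corrected Chao1
  diversity with coverage-based rarefaction (Good's coverage target 0.99);
  Spearman association between diversity and degradation rate.
* **Simulators** (`plastideg.simulate`) — seeded forward models of every
  input (erosion campaigns, BOD bottles, metagenome ORF tables with known
  community composition, Dirichlet-multinomial ASV tables along a rate
  gradient), each with a ground-truth sidecar.

## Worked example

Simulate a five-site film campaign, estimate rates, and project bag
lifetimes:

```sh
$ plastideg simulate erosion --out demo --seed 11
$ plastideg kinetics rates --measurements demo/measurements.csv --out demo/rates.csv
$ plastideg kinetics lifetime --rates demo/rates.csv --out demo/lifetime.csv --bound slowest
$ head -8 demo/rates.csv
# plastideg 0.1.0
# seed: none
# config: 1a2a248fa609
polymer,site,V_mean,V_sd,V_min,V_max,n
PHBH,AKR05,4.586902141714374,0.1500779430478859,4.420681276144869,4.784031573447626,4
PHBH,AMN13,4.5090453647091655,0.23982500669821177,4.258145870064696,4.82712690946796,4
PHBH,BHT03,15.97044537649495,0.6470221101701654,15.319399010275266,16.86227673625626,4
PHBH,BHT08,16.09182024725476,0.814970144337834,15.348218336737634,17.12134697123286,4
```

Rates fall from ~90 μg/cm²/day at the shore site (PJM02) to ~16 at the
bathyal sites (~855 m) and ~4.5 on the abyssal plain (~5500 m) — the
depth attenuation configured in the scenario, recovered from the simulated
weighings to within a few percent. The lifetime table inverts each site's
slowest replicate rate into the days needed to fully degrade the default
3 g bag:

```text
polymer,site,bound,days
PHBH,BHT03,slowest,64.75864303802517
PHBH,PJM02,slowest,11.246364582456506
```

i.e. about 11 days in coastal water and about two months at ~1000 m for
this scenario; a non-degrading material (V ≤ 0) reports an infinite
lifetime rather than an error.

In Python the same worked numbers are one-liners:

```python
>>> from plastideg import kinetics as kin
>>> kin.biodegradation_rate(0.208864, 32, 61)   # shore PHB film, 61 days
107.00000000000001
>>> kin.estimated_lifetime(76.31)               # slowest PHA rate, default bag
13.000438894817089
```

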