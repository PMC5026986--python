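# throughfall

Quantitative attribution of microbial nitrification in incubated
**throughfall** — the rainwater that drips from tree canopies, carrying
washed-off solutes and phyllospheric microbes.  The package is written for
biogeochemists and microbial ecologists who incubate filtered and
unfiltered water samples, measure inorganic nitrogen and nitrate
dual isotopes (δ¹⁸O, δ¹⁵N), and quantify nitrifier marker genes (archaeal
*amoA*) by qPCR, and who want the whole inference chain — from tidy
measurement tables to "how much nitrate did nitrification produce, and do
the independent lines of evidence agree?" — reproducible and tested.

## The model

Atmospherically deposited nitrate is strongly ¹⁸O-enriched (δ¹⁸O ≳ +60 ‰
vs VSMOW).  Nitrate produced by microbial nitrification is not: about two
thirds of its oxygen comes from ambient water and one third from dissolved
O₂, so its δ¹⁸O end member is

```
δ¹⁸O_new = w·δ¹⁸O_water + (1−w)·δ¹⁸O_O2 ,   w = 2/3 ,
```

an interval of [+1.2, +4.5] ‰ for water in [−10, −5] ‰ and O₂ at +23.5 ‰.
Mixing new nitrate into the standing pool pulls the pool's δ¹⁸O from
δᵢ down to δ_f, and the two-end-member mass balance

```
f = (δᵢ − δ_f) / (δᵢ − δ_new)
```

gives the fraction *f* of the final pool that is newly produced;
100·f/(1−f) expresses the same production as a percentage of the
*original* amount, directly comparable to the measured concentration
increase.  Around this core the package provides δ-notation arithmetic and
internal-standard calibration, endpoint nitrogen budgets with a
nitrifying / nitrite-accumulating / inactive classification across filter
treatments, qPCR copy-number normalization with limit-of-quantification
censoring, a seeded synthetic-incubation generator for validation, and a
pipeline (library API + `throughfall` CLI) tying it together.

## Worked example

```python
from throughfall import attribute_nitrification, nitrification_endmember

endmember = nitrification_endmember(water_low=-10.0, water_high=-5.0, o2=23.5)
result = attribute_nitrification(
    delta_initial=74.1, delta_final=49.8, endmember=endmember,
    c_initial=219.0, c_final=332.0,
)
```

prints, via `examples/01_endmember_and_mass_balance.py`:

```
predicted end member: [+1.2, +4.5] per mil
fraction of final pool that is new: 0.333-0.349
new nitrate as % of original amount: 50.0-53.6 %
concentration-based increase: 51.6 %
consistent within 2 pp tolerance: True
```

Reading: a δ¹⁸O drop from +74.1 to +49.8 ‰ over a four-week incubation
implies that one third of the final nitrate pool is new — production worth
50.0–53.6 % of the original nitrate, agreeing with the independently
measured 219 → 332 µM (51.6 %) increase.  Two independent measurements,
one isotopic and one chemical, point at the same amount of nitrification.

The other scripts in `examples/` walk through the nitrogen budget, qPCR
normalization, simulation + parameter recovery, and the full pipeline; the
CLI equivalents are

```
throughfall fixture --name cj1_printed --out in/
throughfall analyze --config run.yaml
throughfall simulate --scenario cj1_like --seed 1 --out sim/
```

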