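# flyndj

Simulation and inference toolkit for *Drosophila* X-chromosome
nondisjunction (NDJ) genetics: the assay stack used to screen oocytes for
defects in sister-chromatid **cohesion maintenance** during meiotic
prophase.

## Who this is for

Fly geneticists and quantitative biologists who run (or want to model)
the classical X-NDJ test cross, the recombinational-history assay on
Diplo-X exceptional females, crossover-frequency mapping, or a
multi-arm RNAi screen with germline drivers of different timing
(nanos: from premeiotic S phase; matα: meiotic prophase only) in the
sensitized *mtrm*<sup>KG</sup>/+ background, where the achiasmate backup
segregation pathway is disabled.

## The statistics at the core

**Doubled-E %NDJ estimator.** Assay females are crossed to attached-X^Y,
Bar males. A zygote's X dosage determines viability: metafemales
(diplo-X ovum + X^Y sperm) and nullo-X zygotes die, so exactly half of
exceptional zygotes are ever counted. With N normal and E exceptional
viable progeny,

```
%NDJ = 100 · 2E / (N + 2E)
```

If a fraction π of ova are exceptional, viable progeny are exceptional
with probability q = (π/2)/(1 − π/2), and 2q/(1 + q) = π exactly — the
estimator inverts the viability filter. Confidence intervals come from
pushing the Clopper–Pearson interval on q through that transform.
Two-group comparisons use a pooled delta-method z-test plus a
conditional parametric bootstrap (E\* ~ Binomial(T, q₀) per group under
the pooled null), two-sided.

**Recombinational history.** Each surviving Diplo-X female is phenotyped
for *sc cv f car* and her sons are genotyped; her two chromatids are
deduced (sons report chromatids directly; at most two son classes can
exist). The centromere-proximal marker *car* splits the error type:
car heterozygous ⇒ two homologs (MI error), car homozygous ⇒ two
sisters (MII error). A chromatid is recombinant iff its scored alleles
match neither parental arrangement. The readout is
1000 · (Diplo-X females with ≥1 recombinant chromatid) / (total NDJ-test
progeny), compared between genotypes by two-sided Fisher's exact test.

**Map distances.** cM = 100 · recombinants / sons per scored interval
(raw, no mapping function), total = sum over intervals; between-genotype
comparison by Fisher's exact test per interval and on pooled events.

**Screen calling.** Per gene, three arms (control / nanos-KD / matα-KD)
are compared at α = 0.05 (two-sided, no cross-gene correction):
significant NDJ increase with matα but not nanos ⇒ *prophase-specific*
(cohesion-rejuvenation signature); both significant ⇒ compare drivers;
knockdown arms under the sterility threshold (50 viable progeny) are
excluded rather than called.

A forward simulator of single-oocyte meiosis backs everything: per-
interval crossovers at chromatid-level rate r (bivalent probability 2r),
whole-bivalent chiasma destabilization with probability `p_arm_loss`,
premature pericentric cohesion loss at MII with `p_mii_loss`, and an
achiasmate backup pathway that rescues unconnected homologs — disabled
to model the *mtrm*<sup>KG</sup>/+ screen background. Simulation truth
(homolog of origin, exchange history) is carried through so every
inference rule can be scored against it.

## Worked example

`examples/01_ndj_assay.py` simulates a control and a knockdown arm
(2000 viable progeny each) and prints:

```
control (no driver)  N= 1973  E=  27  %NDJ=  2.66  [95% CI 1.77-3.84]
mata KD              N= 1730  E= 270  %NDJ= 23.79  [95% CI 21.48-26.20]

KD vs control: p_monte_carlo=1.00e-04 (z-path p=6.27e-49)
```

Reading: the control arm's 27 exceptional flies double to an estimated
2.66% gamete-level NDJ; elevated arm-cohesion loss in the knockdown arm
pushes that to 23.8%, and both test paths call the difference (the
bootstrap p is floored at 1/(B+1) with B = 10,000 replicates). The other
examples walk the recombinational-history assay
(`02_recombinational_history.py`: MI recombinant errors rise ~13-fold,
MII errors stay flat), crossover mapping (`03_crossover_map.py`: the
13.7 / 23.0 / 5.8 cM placeholder map is recovered and knockdown leaves
it unchanged), and a seven-gene synthetic screen with known truth
(`04_synthetic_screen.py`).

A thin CLI mirrors the library for TSV-based work:
`flyndj fixtures --seed 7 --out bundle/` writes a full synthetic dataset;
`flyndj ndj estimate --counts bundle/ndj_counts.tsv`,
`flyndj screen run --manifest bundle/screen_manifest.tsv --out results.tsv`,
etc.

## Layout

| path | contents |
|---|---|
| `src/flyndj/meiosis.py` | oocyte simulator (vectorized + per-bivalent reference path) |
| `src/flyndj/crosses.py` | NDJ test cross, viability filter, Diplo-X genotyping cross |
| `src/flyndj/stats.py` | doubled-E estimator, two-group tests, Fisher's exact |
| `src/flyndj/recomb.py` | chromatid deduction, MI/MII classification, per-1000 frequencies |
| `src/flyndj/linkage.py` | interval scoring, map distances, map comparison |
| `src/flyndj/screen.py` | decision table, synthetic screen generator, screen runner |
| `src/flyndj/experiments.py` | end-to-end simulated assays with truth channels |
| `src/flyndj/io.py`, `cli.py` | TSV schemas, flat configs, `flyndj` command |

See `docs/methods.md` for the model, its assumptions, parameter
defaults, and what the synthetic data does and does not emulate.
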