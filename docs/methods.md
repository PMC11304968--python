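# Methods

## The meiotic model

A bivalent is represented as four chromatids: two sisters per homolog,
identity anchored at the centromere (the homolog-of-origin tag never
changes under crossing over and is the MI/MII ground truth). The
maternal genotype is the classical marked-X heterozygote: one homolog
carrying only *y*, the other *y sc cv v f car*, with the centromere
proximal to *car*.

**Crossovers.** Each physical map interval independently receives at
most one crossover, with bivalent probability 2r, joining a uniformly
chosen non-sister pair and exchanging the segments distal to the
interval. r is the chromatid-level recombination fraction: a bivalent
exchange at rate 2r leaves 2 of 4 chromatids recombinant, recovering r
per gamete. There is no chromatid or crossover interference and no
obligate-crossover mechanism in the raw sampler; an optional
`obligate_chiasma` mode resamples until at least one exchange exists,
emulating crossover assurance. With no exchange in *y–sc* or *car–CEN*
by default, the scored intervals carry the standard-map placeholder
fractions sc–cv 0.137, cv–f 0.23, f–car 0.058 (map values are
configuration, not constants). Because *v* sits inside cv–f, the 0.23
is split equally across cv–v and v–f with r\* chosen so the composite
chromatid-level fraction is exactly 0.23 (r\* + r\* − 2r\*² = 0.23,
r\* ≈ 0.1326); double exchanges inside cv–f therefore occur naturally
and are invisible at the scored flanks, which is the assay's documented
blind spot.

**Segregation.** Arm-cohesion loss is modelled as whole-bivalent chiasma
destabilization: with probability `p_arm_loss` a chiasmate bivalent
becomes unconnected. Unconnected homologs (achiasmate or destabilized)
are rescued by the heterochromatin-mediated achiasmate pathway with
probability `backup_efficiency` when enabled; otherwise each homolog
segregates to the ovum pole independently (diplo-X and nullo-X MI ova
with probability 1/4 each). The backup pathway rescues the segregation
outcome without touching haplotypes. After a normal MI, premature
pericentric cohesion loss (`p_mii_loss`) lets sisters segregate
independently (diplo/nullo MII ova, 1/4 each). Consequences used as
internal checks: with universal chiasma loss and no backup, half of all
ova are exceptional; with perfect backup, only MII errors remain, at
frequency `p_mii_loss`/2.

## Crosses

The NDJ test cross assumes equal X^Y and nullo sperm classes and no
meiotic drive; zygote viability is purely X-dosage-determined, so
exactly half of exceptional zygotes die — the origin of the doubled-E
correction. The Diplo-X genotyping cross transmits the mother's two
chromatids intact (probability 1/2 each, no new recombination): sons
are treated as direct chromatid reporters, matching how the deduction
rules read them. X/0 male sterility is irrelevant to counting and
ignored; autosomes, balancers and the Bar marker exist only as class
labels.

## Inference rules and their failure modes

The chromatid-pair deduction requires ≤2 distinct son classes and full
consistency with the mother's visible phenotype (recessive markers show
only when homozygous); contradictions raise addressable errors. A
single observed class is called a homozygous pair at high confidence
only when ≥8 sons were scored (probability < 0.004 of missing a second
class at 1/2 transmission) or when every scored locus is visibly
homozygous; otherwise the record is flagged low-confidence and excluded
from frequency numerators and denominators (the exclusion policy is
this package's choice and is logged). *y* is uninformative (both
maternal X's carry it) and *v* is carried in the genotype but never
scored.

The *car* rule misclassifies MI/MII exactly when an f–car exchange
decouples *car* from the centromere; the misclassification rate is
bounded by the f–car recombinant fraction (≈0.058 at the default map)
and checked against simulation truth. The recombinant-missegregation
frequency undercounts by construction — only two of four chromatids are
sampled (a single-exchange MI diplo ovum shows no recombinant chromatid
with probability 1/4) and intra-cv–f doubles are invisible — so
measured frequencies are a lower bound on crossover-bearing
missegregants; the test suite asserts the strict inequality.

## Statistical choices

The two-group NDJ comparison offers two paths sharing one null (the
pooled viable-exceptional rate q₀): a delta-method z on the doubled-E
proportion with pooled variance, and a conditional parametric bootstrap
(E\* ~ Binomial(Tᵢ, q₀), add-one p-value (r+1)/(B+1), default
B = 10,000). Neither is claimed to be any previously published test's
exact formula; the decision rule (two-sided, α = 0.05) is what matters,
the two paths agree within 0.02 whenever both exceptional counts are
≥10, and type-I error is calibrated to 5% ± 1.5% on matched null arms.
The bootstrap path is the reference; its discreteness at small E makes
it slightly conservative. Internally the two groups are put in a
canonical order before resampling so the p-value is exactly invariant
under swapping them. No multiple-testing correction is applied across
screen genes, matching per-gene α usage; callers can correct the
returned p-value columns themselves.

Fisher's exact test is implemented by direct hypergeometric enumeration
(two-sided = sum of all tables no more probable than observed, with a
1 + 1e-7 relative guard against floating-point ties — the GraphPad/scipy
convention); scipy's implementation serves as an independent
cross-check in the tests, to 1e-12. Zero-margin tables return p = 1
with a warning. %NDJ confidence intervals are Clopper–Pearson on
q = E/(N+E) pushed through the monotone doubled-E transform; level
fixed at 95%.

## The synthetic-data generator as study conditions

Screen and recombinational-history experiments simulate the sensitized
background: backup disabled, `obligate_chiasma` on (keeping
backup-disabled control arms at the few-percent %NDJ real sensitized
controls show; without crossover assurance the no-interference model
makes ~35% of marked-X bivalents achiasmate, far above real flies — a
known limitation of interference-free crossover placement). Free
parameters the assays do not pin down were fixed once: baseline
`p_arm_loss` 0.04 (control arms ≈ 2% gamete-level NDJ),
strong-knockdown `p_arm_loss` 0.5, S-phase-plus-prophase arms (matα
0.4, nanos 0.7 — the earlier driver hits harder), `backup_efficiency`
0.95 where the pathway is intact, sterile arms ~12 viable progeny
against a threshold of 50, 12 sons genotyped per Diplo-X female.
Experiments collect progeny until a target viable count, mirroring how
crosses are scored to a total.

What the generator does **not** emulate: crossover interference,
per-vial/brood/maternal-age structure, phenotyping error, meiotic
drive, driver expression kinetics (drivers enter only as which arm's
parameters move), autosomal events, or any sequence-level process.
Passing tests therefore validate the estimators, the deduction rules
and the decision logic under the stated sampling model — not the
biology of any particular gene.

## Screen decision table

Positive calls require a significant *increase* (two-sided p < α and
knockdown point estimate above control) — a decrease routes to its own
category — so the analytic null rate for a prophase-specific false call
is (α/2)(1 − α/2) ≈ 0.024 per gene, which replicated null screens
reproduce. Arm-vs-arm ordering (nanos higher than matα) uses the same
dual-path test. The sterility threshold (50 viable progeny,
configurable) has no canonical value; arms under it carry no p-values
and the gene is excluded from prophase-specific calling, whatever its
matα arm shows.

## Problem sizes and numerics

Default verification sizes: 50,000 ova for estimator recovery, 20,000
for the random-segregation limit, 10,000 sons for map recovery
(binomial 95% CI criterion), 2,000 null trials × 2,000 bootstrap
replicates for calibration (path agreement measured at 20,000
replicates, where Monte-Carlo noise no longer dominates), 50 replicate
20-gene screens, 200 replicate two-arm recombinational-history
experiments. The acceptance script uses the same or lightly reduced
replicate counts and finishes in seconds. All sampling in a simulation
call is drawn from one numpy Generator in a fixed order; scalar and
vectorized samplers implement the same process and are compared
statistically, not draw-for-draw. Degenerate inputs fail loudly:
sterile crosses raise rather than report 0%, zero-margin tables warn,
config errors name the offending field, and malformed son codes are
skipped with a count.
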