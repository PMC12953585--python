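# Methods

`lupus_popgen` re-implements, as one tested toolkit, the population-genomic
inference stack used to resolve the history of the three deeply diverged
grey-wolf lineages of Asia (Indian, Tibetan, Holarctic) and of the recently
admixed southwestern Asian population. All analyses operate on a genotype-level
data model (biallelic SNPs, diploid calls); read-level quantities (depth,
genotype likelihoods) from the original sequencing pipelines are out of scope
and are represented by site-quality and missingness knobs instead. This note
documents the models, the defaults and why, the numerical choices, and what
the simulation-based tests do and do not establish.

## The synthetic cohort generator

Every test cohort comes from `sim.simulate_cohort`, a coalescent simulation
(msprime) under an explicit `DemographicModel`. The default model
(`default_wolf_model`) encodes the study conditions:

| parameter | value | note |
|---|---|---|
| mutation rate | 4.5e-9 /bp/generation | wolf pedigree estimate |
| generation time | 4.4 years | |
| Indian split | 100,000 y (~22,700 gen) | deep lineage |
| Tibetan split | 120,000 y | earliest-diverging lineage |
| SWAsia–Central split | 10,300 y (~2,340 gen) | |
| Indian→SWAsia pulse | proportion 0.11 at 6,000 y | the admixture signal under test |
| outgroup splits | 1.0 and 2.0 My | dhole / Andean-fox-like polarization anchors |
| N_e | Indian/Tibetan/SWAsia 5,000; Central & ancestor 15,000 | order-of-magnitude wolf values; config, not claims |
| genome | 10 chromosomes × 5 Mb, r = 1 cM/Mb | desk scale |

N_e values are deliberately round: small for the long-isolated lineages and
the southwestern population, larger for the connected Holarctic population
and the ancestor. The genome is a miniature (50 Mb vs ~2.4 Gb): tests
calibrate the *machinery*, not the biology, and every size used is stated in
the tests themselves.

What the generator emulates: three-lineage structure, a dated admixture
pulse, deep outgroups, per-individual autozygosity (via `plant_roh`, which
forces planted tracts to homozygosity), random missingness, and SnpEff-like
impact annotations (`assign_impact_annotations`, multinomial over
HIGH/MODERATE/LOW/MODIFIER at proportions 0.001/0.01/0.05/0.939, roughly the
genome-wide class frequencies among SNPs). What it does not emulate:
selection (deleteriousness is annotation-only, so load analyses are
accounting tests, not selection tests), sequencing error, reference bias,
genotype-likelihood uncertainty, and realistic recombination-map structure.
Passing tests therefore demonstrate correct statistics and calibrated errors
on idealized genotypes, not robustness to real-data artifacts.

## D-statistics

`dstat` computes frequency-based ABBA-BABA tests for quartets
(((P1,P2),P3),P4). Sites are polarized by the P4 consensus (majority allele
among non-missing outgroup calls); sites where the outgroup is polymorphic or
missing are skipped, as are sites where any quartet population has no called
allele. With derived-allele frequencies p_i,

    abba = (1-p1) p2 p3 (1-p4),   baba = p1 (1-p2) p3 (1-p4),
    D = (Σbaba − Σabba) / (Σbaba + Σabba),

so an excess of derived sharing between P2 and P3 gives D < 0 — the sign
convention is pinned to this observable rather than to any particular tool's
internals. Standard errors are delete-one-block jackknives over contiguous
blocks (default 5 Mb), weighted by informative sites per block using the
Busing unequal-m formula; Z = D/SE and |Z| > 3 is the significance rule.
Single-individual quartet members are supported (frequencies in {0, ½, 1}).

Calibration (tested): on 100 no-gene-flow cohorts |Z| < 3 in ≥95% of
replicates, and the mean jackknife SE is within 30% of the replicate SD of D.
Power (tested): with the 0.11 pulse, the (((Central,SWAsia),Indian),Outgroup)
quartet yields Z < −3 in ≥90% of replicates. The null calibration uses the
Tibetan lineage as P4 — a valid outgroup to the (Central, SWAsia, Indian)
trio under the model — which keeps 100 replicates tractable; the power test
uses the deep canid outgroup.

## Topology weighting

`topoweights` cuts each chromosome into consecutive 100-SNP windows
(terminal remainders dropped), attaches a bp-overlap-weighted local
recombination rate to each window, builds a neighbor-joining tree on
haplotype p-distances per window, and decomposes each tree into exact
weights over all (2k−5)!! unrooted topologies of k population groups
(3 for k=4, 15 for k=5, 105 for k=6). Weighting iterates the full Cartesian
product of one tip per group and matches the induced topology by its split
set — no subsampling, so weights are exact and sum to 1.

Numerical choices: tips are sorted lexicographically before NJ so results do
not depend on input order; internal branches of length ≤1e-12 are collapsed,
so signal-free windows yield multifurcations (identical haplotypes give a
star tree), and an unresolved induced topology distributes its count equally
over all compatible binary resolutions, preserving the sum-to-1 invariant.
NJ on p-distances replaces maximum-likelihood window trees: at 100-SNP scale
the consumer of these trees only needs topologies, and NJ is deterministic
and dependency-light. Windows are stratified into low (<0.2), medium
([0.2, 2]) and high (>2 cM/Mb) recombination classes; both printed boundary
values are assigned to the medium class.

## Runs of homozygosity and inbreeding timing

`roh.detect_roh` is a two-state HMM over one individual's calls: the
Hardy-Weinberg state emits heterozygotes with probability 2f(1−f) at the
fixed allele frequency f = 0.4; the autozygous state emits them at an error
rate (1e-4). The per-site transition probability defaults to 1e-5 — chosen
so the posterior error floor deep inside a clean tract (≈ transition²/2)
stays well below the phred-80 segment-quality filter; with a genetic map it
is scaled by the local-to-mean rate ratio, honoring recombination
heterogeneity. Segments are maximal runs of sites with autozygosity
posterior > 0.5, extended to midpoints between flanking sites, then filtered
at ≥100 kb length and ≥80 quality (quality = mean per-site phred of the
autozygous posterior, capped at 100/site).

In a cohort containing deeply diverged taxa, most SNPs are invariant within
any one population and carry no autozygosity information;
`population_informative_sites` restricts the HMM to sites segregating in the
focal individual's population (the pipeline applies this automatically).

Segment lengths are binned 0.1–1 / 1–5 / 5–10 / 10–100 Mb; F_ROH is total
ROH length over genome length. Timing uses g = 100/(2 r L) generations for a
segment of L Mb at r cM/Mb (genome-wide mean 1.34 cM/Mb): L = 5 Mb dates to
7.46 ≈ 7 generations. The formula assumes a constant recombination rate;
outputs are estimates, not dates.

Recovery (tested): planted tracts ≥1 Mb are recovered at ≥90% base-level
sensitivity and ≥95% precision over 20 replicate cohorts.

## Heterozygosity and inbreeding coefficient

`diversity.heterozygosity` is the direct ratio of heterozygous to callable
sites. The inbreeding coefficient is a moment estimator,
F = 1 − observed het / expected het, with allele frequencies taken from the
rest of the individual's population (the focal individual is excluded to
avoid self-bias). Only sites segregating among those reference members are
used, and the per-site expectation is the unbiased 2pq estimator
(factor c/(c−1)) multiplied by the estimated ascertainment probability
1 − p^c − q^c, so observed and expected condition on the same site set. This
correction matters at small panels; with ~11 reference diploids an outbred
individual reads |F| < 0.1 and a 25% planted autozygous fraction reads
F = 0.25 ± 0.05. F and F_ROH correlate strongly (Spearman ρ > 0.8 in tests).

## Genetic load

`load.polarize_sites` pseudo-haploidizes two outgroup genomes (one allele per
genotype, heterozygotes resolved uniformly with a seed; missing drops the
site) and keeps only sites where the two agree; the agreed allele is
ancestral, the cohort's other allele derived and — at HIGH or MODERATE
impact — assumed deleterious. Per individual: total load = derived alleles
at deleterious sites (2 per homozygote, 1 per het); realized = the
homozygous part; masked = the heterozygous part, so
total = realized + masked holds exactly. Loads are counted in alleles so the
identity is exact; a per-site variant (`unit="site"`) is exposed because
axis units in published figures are often ambiguous between the two.
Per-category derived counts are normalized per 100,000 MODIFIER (putatively
neutral) derived alleles to compare individuals with different totals.

The drift prediction is tested, not assumed: in simulations with a recent
50-fold bottleneck (annotation-only deleteriousness, drift the only force),
the bottlenecked population shows higher realized and lower masked load in
≥80% of replicates.

## Folded SFS and demographic model comparison

`sfsfit.build_folded_sfs` constructs the observed folded joint spectrum with
per-block complete-data downsampling: within each genome block (2 Mb by
default), each population contributes its least-missing individuals (ties by
sample order), only SNPs complete in that selection are retained, and
monomorphic-in-subsample sites are counted separately. Folding merges each
joint cell with its full complement; the side with the smaller total derived
count keys the cell, with exact half ties going to the lexicographically
smaller index. A second, unlinked spectrum takes one retained SNP per block
(uniform, seeded) for likelihood recalculation.

Three candidate origins of the southwestern population are parameterized
over (Indian, SWAsia, Central): **A** strict bifurcation, **B** = A plus an
Indian→SWAsia pulse (adds proportion and time), **C** SWAsia founded as a
single-generation hybrid of Indian and Central parents (contribution
parameter). Sizes and the deep Indian split are fixed at the study
conditions; free parameters default to the split time (A), plus pulse
proportion and time (B), or hybrid contribution (C).

Expected spectra come from coalescent simulation of unlinked loci
(`simulate_folded_counts`): site mode drops mutations and tabulates a genuine
multinomial spectrum (used for the neutral 1/i check); branch mode tabulates
the branch-length spectrum of the same genealogies — the identical
expectation with far less Monte-Carlo noise — and is the default inside the
optimizer. Empty polymorphic cells get a pseudocount of 1/(10·n_loci) before
normalization. Fitting maximizes the composite log-likelihood
Σ m_cell log p_cell by a coarse log-spaced grid followed by Nelder-Mead in
log-parameter space, with every evaluation reusing one simulation seed
(common random numbers), making fits deterministic and the objective smooth
in the parameters. Model comparison recomputes the likelihood on the
unlinked spectrum at each optimum, then AIC = 2k − 2 lnL_unlinked,
ΔAIC against the minimum, and Akaike weights exp(−ΔAIC/2) normalized.

Desk-scale sizes: test fits use 600 unlinked loci per expected spectrum and
50-Mb data genomes; unlinked SNP selection uses 250-kb blocks there, because
2-Mb blocks on a 50-Mb genome would leave ~25 unlinked SNPs — too few to
contrast any models (the 2-Mb default matches whole-genome use). With these
sizes, model B is preferred over A on B-simulated data in ≥70% of replicates
and the SWAsia–Central split time is recovered within a factor 1.5 in ≥80%.

## Pipeline

`pipeline.run_pipeline` drives simulate → filter → the six analysis stages
from a YAML-loadable config, writing one TSV per stage with `#key=value`
headers, plus a JSON manifest (seeds, config echo, SHA-256 of every output).
A failing stage is recorded without aborting the others. All outputs are
byte-identical across reruns with the same config and seed; wall-clock
timings go only to `run.log`, the single non-deterministic file. The
`lupus-popgen` CLI exposes each stage and the full run.

## Known limitations

* Genotype-level only: no genotype likelihoods, no depth-aware filters.
* No selection in the simulator; load results demonstrate bookkeeping and
  drift, never purging.
* The ROH HMM simplifies the genotype-likelihood emissions and
  genetic-map-scaled transitions of production callers; its parameters are
  calibrated to the quality/length filters used here.
* Expected-SFS precision is Monte-Carlo limited; fits use common random
  numbers, so *differences* between parameter values are much better
  resolved than absolute likelihoods.
* Desk-scale genomes mean all power statements are scaled-down analogues of
  whole-genome analyses, not reproductions of them.
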