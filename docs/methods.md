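# Methods

This note documents the models and procedures implemented in `pangem`, the
choices made where the design was genuinely open, and what the synthetic
study conditions do and do not establish about real data.

## Synthetic study design

`pangem.synth.generate_world` builds a strain panel with full ground truth.
Its defaults define the study conditions used throughout the tests and the
acceptance script:

| parameter | default | rationale |
|---|---|---|
| `n_strains` | 24 | the size of a typical phenotyped panel |
| `n_core_families` | 30 | enough to gate a universal pathway and dominate row sums |
| `n_accessory_families` | 45 | leaves head-room for 7 accessory pathways of ≤ 4 reactions |
| `n_rare_families` | 10 | strain-private content (column sum exactly 1) |
| `accessory_presence_prob` | 0.7 | mid-range retention: phenotypes vary without being degenerate |
| `allele_mutation_rate` | 0.02 /site | keeps within-family identity ≈ 96–98%, well above the 90% clustering and 60% orthology cutoffs |
| `protein_length_range` | 120–250 aa | short enough for fast alignment, long enough that the ~2× member-to-representative distance never breaches 90% (real proteome mean is ~332 aa) |
| `n_substrates` / `n_pathways` | 8 / 8 | one linear catabolic pathway per substrate; pathway 1 is gated by core families so every strain grows on it (the glucose analogue) |
| `grower_signal_amplitude` / `baseline_signal` / `noise_sd` | 200 / 10 / 5 signal units | OmniLog-like scale; signal-to-noise ≈ 40 |
| `n_timepoints` / `total_time_h` | 97 / 48 h | one reading per 30 min over a 48-h run |
| `n_control_wells` / `n_replicates` | 3 / 3 | triplicate plates, controls pooled per strain |

Grower wells follow a logistic curve rescaled to rise exactly from the
baseline to the amplitude over the run (10–90% of the rise spans ~37% of
the run, so a window-51 Savitzky-Golay filter perturbs the maximum by
< 0.2%); non-growers and controls sit at the baseline. All wells receive
i.i.d. Gaussian noise. Gaussian noise is an assumption of this generator,
not a claim about plate-reader hardware. Randomness flows from one root
seed through named child streams (genomes, alleles, network, plates,
dropout), so adding a stage never perturbs another stage's draws and a
fixed seed reproduces the world byte for byte.

Each pathway reaction is gated by a single, distinct gene family (core
families for the universal pathway, accessory families otherwise), so
losing one family breaks exactly one substrate and truth recovery is
interpretable. Amino-acid substitutions are uniform over the 19
alternatives; indels are off by default (`indel_rate` exists for stress
tests) because the alleleome treats alleles as unique sequences, for which
substitutions suffice. At generation time the declared truth table is
re-verified by running FBA on every strain-restricted network.

**What this does not emulate:** real signal kinetics (lag/diauxie,
non-Gaussian and autocorrelated noise), paralog expansion, horizontal
transfer, genome mis-assembly, promiscuous or branched pathways, and
regulatory effects that decouple gene content from phenotype. Passing
tests therefore demonstrate correctness of the computational procedure
under its stated assumptions, not field performance on real panels.

## Growth calling

Traces are smoothed by a Savitzky-Golay filter. The conventional window of
50 is even; classical SG needs an odd window, so the effective window is 51
(logged). A constant trace is preserved exactly and any polynomial of
degree ≤ 3 is reproduced to machine precision. The per-well statistic is
the maximum smoothed signal. Control maxima are pooled across a strain's
replicate plates; the control spread uses the sample (n−1) standard
deviation because control counts are small. Each substrate well gets
`z = (max − μ̂)/σ̂` and a one-sided upper-tail normal p-value, Bonferroni
multiplied by the number of substrate wells on its own plate (per-plate m).
A cell is called growth only if the adjusted p is strictly below alpha in
**every** replicate (a majority rule is available). Ties at exactly alpha
are no-growth. Degenerate controls (σ̂ = 0) raise an error by default; an
explicit flag substitutes a floor of 1e-6·|μ̂|.

A calibration point worth stating plainly: the per-well z-test alone is
anti-conservative. The maximum of a smoothed noise trace is right-skewed,
and σ̂ estimated from a handful of control wells has heavy t-like error, so
single-replicate calling shows a family-wise false-call rate far above
alpha. What controls the family-wise rate in practice is the conservative
all-replicates rule: requiring significance in all three replicate plates
drives the measured rate on all-null plates to ≈ 0.02 ≤ alpha. Panels
assayed without replication should not expect the nominal Bonferroni
guarantee from this caller.

Compound-group summaries: a strain's activity on a group is the fraction of
the group's substrates called growth; the group's metabolic activity index
is the mean of that fraction over strains. The module also carries the
PM01/PM02A panel bookkeeping (eight groups totalling 190 substrates, 15
extra agar-assayed aromatics, 144 substrates with model identifiers).

## Pan-genome and alleleome

Clustering is greedy and longest-first: records sorted by decreasing length
(ties by id) join the earliest-founded family whose representative they
match at ≥ 90% identity, else found a new family. Identity is matches /
alignment columns on the optimal global alignment (BLOSUM62, linear gap
penalty −8 per column). No k-mer prefilter is used; a length-ratio bound
(identity ≤ min/max length) skips hopeless alignments, which is exact. The
90% default matches the clustering tool convention the field uses. Note a
consequence of clustering against representatives: two members can each be
within 10% of the representative but ~20% of each other, so very short
proteins at high mutation rates can split families — a property shared
with the original greedy tool.

The core-genome curve orders strains by decreasing shared-family count
(ties lexicographic) and reports the running intersection; it is
non-increasing for any ordering and its final value is the all-strain
intersection regardless of ordering. Strain blocks use
Jaccard distance + average linkage, cut to k clusters, labels renumbered in
first-appearance order for determinism.

Alleles are unique sequences within a family, ranked by distinct-strain
count (a strain with two paralogous sequences counts once in each allele's
strain set). Alleles sharing a count get suffixes `count-1, count-2, …` in
rank order. Dominant alleles are those in strictly more than 50% of
strains. Substitutions against the dominant allele are conservative iff
both residues share a group in {AVLIMC}, {FWY}, {ST}, {NQ}, {DE}, {KRH},
{G}, {P} — a standard hydrophobic/aromatic/hydroxyl/amide/charge partition;
indel columns are tallied separately. Clade splits use neighbor-joining on
p-distance (differing residue pairs / aligned residue columns; unequal
lengths are globally aligned first). Maximum-likelihood tree inference with
bootstrap was deliberately replaced by NJ + midpoint rooting: it is
deterministic, dependency-free at desk scale, and sufficient to assign
major/minor clades; bootstrap support is out of scope. Midpoint rooting is
implemented on the diameter edge directly; when the midpoint falls exactly
on a node (star-like families), the root is nudged into the tip-side edge
so the root always bifurcates and the dominant allele stays in the major
clade. The major clade has more alleles; ties go to the larger total strain
count.

## Strain models

The metabolic network container mirrors the COBRA JSON schema (compartments
c/p/e, bounded reactions, GPR strings, biomass objective); files written by
`save_json` load in cobrapy, which the test suite exploits as an
independent FBA oracle. GPRs are parsed once at load time into and/or
trees; evaluation is total, and an empty rule means the reaction is kept
regardless of gene content (non-enzymatic convention).

FBA maximises the biomass flux subject to S·v = 0 and bounds (HiGHS LP).
Environment policy: the chosen carbon exchange's lower bound is −uptake
(default 10 mmol/h/gCDW), medium exchanges are open at their stated rates,
all other exchanges are closed to uptake but open to secretion. Growth
means objective > 1e-6 /h (configurable). Only the objective value is
contract-bearing; alternative optimal flux vectors are acceptable.

Orthology replaces heuristic local search with exact global alignment:
deterministic and correct at desk scale, at the cost of speed and of using
global rather than local identity for the 60% cutoff. Best hits are
highest-identity matches (ties to the lexicographically first id); a pair
is kept iff mutually best and ≥ 60%. Derivation removes pan genes without a
BBH pair, re-evaluates every GPR, drops reactions whose rule turns false,
prunes orphan metabolites, and records provenance.

Gap-filling is uniform-cost minimum-cardinality: binary indicators gate
candidate reactions (v bounds scaled by y), a MILP minimises Σy subject to
mass balance and biomass ≥ the required growth. Two numerical choices
matter. First, the MILP's growth requirement is floored at 1e-3 because a
1e-6 threshold sits inside the solver's integer-feasibility tolerance;
every returned set is then verified by an exact LP at the true threshold,
and the floor escalates if verification fails. Second, ties among
minimum-cardinality sets are resolved to the lexicographically smallest
reaction-id set by greedily forcing candidates in id order and re-solving
the cardinality MILP — exact, if slower than a weighted objective.
Pipeline refinement gap-fills only cells where the assay says growth and
the model says no; false positives are left standing, as they reflect
content the pruning kept.

Reaction classes across a panel: core iff frequency ≥ 0.98, rare iff
< 0.10, accessory otherwise (the ≥/<
boundary convention is stated because published wordings overlap at 98%).
MCA uses the indicator-matrix formulation (present and absent category per
reaction), correspondence analysis via SVD of the standardised residual
matrix; zero-count categories are dropped (standard practice — they carry
no mass); row principal coordinates and principal-inertia fractions are
reported.

## Pipeline and reproducibility

`run_pipeline` executes simulate → call → pan-genome → alleleome → derive →
gap-fill → validate → report. Every stage persists its outputs (CSV/TSV/
JSON/FASTA/newick, floats at 17 significant digits where relevant) into the
run directory and every report number is recomputable from those
intermediates; re-running with the same seed reproduces the report byte for
byte. Delta tables against a reference model report absolute differences
and percent increases rounded to the nearest integer. The CLI is a thin
dispatcher over the stage functions.

Problem sizes used by the test suite and acceptance script — 24-strain
default worlds, 1,000 all-null plates for calibration, 200 plates for
power, 8-candidate gap-fill instances checked against exhaustive
enumeration — were chosen as the smallest sizes at which the statistical
claims are meaningfully exercised.

## Known limitations

- Greedy clustering against representatives can split short, fast-evolving
  families (see above); it never merges unrelated toy families at 90%.
- The z-test caller's nominal type-I guarantee depends on replication; see
  the calibration note.
- Gap-filling is uniform-cost; a weight map is accepted but no
  thermodynamic or likelihood weighting is implied.
- NJ clade splits approximate, and do not reproduce, likelihood-based
  phylogenies on real alleles.
- The toy universal network has linear, substrate-private pathways; none of
  the degeneracy of real metabolic networks (isozymes, promiscuity, shared
  intermediates) is represented.
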