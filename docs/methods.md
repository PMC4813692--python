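# Methods

This note documents the models, algorithms and numerical choices behind
`xlfold`, in the order data flows through the pipeline: cross-link
identifications → error control → distance restraints → conformational
search → model selection → validation analyses.  It also describes what the
synthetic-data generator does and does not emulate, and therefore what
passing tests establish about real data.

## Cross-link data model and target-decoy FDR

Photo-cross-linkers of the sulfo-SDA type have asymmetric chemistry: an
NHS-ester end reacting with lysine, serine, threonine, tyrosine or the
protein N terminus, and a photo-activatable diazirine end whose carbene
inserts into essentially any nearby residue.  `xlink_data` models each
peptide-spectrum match (PSM) with both linked sites, the search score, and a
target/decoy class: TT (both peptides target), TD (one decoy) or DD (both
decoys).

False discovery rates are estimated per score threshold *s* over all
matches with score ≥ *s* as

    FDR(s) = max(0, TD(s) − DD(s)) / TT(s),

the standard accounting for cross-link searches with two peptides per
match: a false TT match is estimated by TD − DD because a random false match
picks each peptide independently from target and decoy space.  q-values are
the running minimum of FDR from the most permissive threshold upward, so
they are monotone non-increasing with score.  Ties share one threshold.
When the input carries only a single target/decoy flag the estimator falls
back to FDR = D/T (`mode="td"`); both modes are explicit configuration, and
the TT/TD/DD form is the default.  If no target match is at or above a
threshold the FDR there is undefined and reported as 1.0.

PSMs are collapsed to unique unordered residue pairs keeping the best
(highest) score and its q-value; decoy matches never enter the pair list.
Pairs are canonicalised with the smaller residue index first while each
site keeps its end-chemistry label, because the same residue pair can be
observed with either end carrying the NHS ester.

Modeling-ready constraint lists keep links with q ≤ 0.20 (a deliberately
permissive cut: many slightly noisy constraints beat few clean ones for
topology modeling) and sequence separation **strictly** greater than 12
residues — short-range links mostly restate secondary structure and carry
little tertiary information.

## Lorentzian distance restraints

A cross-link bounds the Cα–Cα distance d between its residues: satisfied
when l < d ≤ u with l = 1.5 Å and u = 20 Å by default (the maximal
through-space reach of long side chains plus the SDA spacer plus
flexibility).  The violation v(d) is 0 inside the band, l − d below and
d − u above.  The energy reward is the bounded Lorentzian

    E(d) = E_max · w² / (w² + v(d)²),

with half-width w = 1 Å: the full bonus E_max on the plateau, E_max/2 at one
half-width of violation, and a vanishing contribution for v ≫ 2w (at v = 2w
the bonus is already down to E_max/5).  Because the penalty for violating
any single restraint saturates, a grossly wrong (false-positive) restraint
is effectively ignored and the term maximises the *number* of satisfied
restraints rather than fitting exact distances.  The bonus is subtracted
from the search energy (lower energy = better).  The algebraic form above is
the simplest function satisfying all the stated properties (exact plateau,
half-value at v = w, monotone decay to zero) and is used throughout.
A distance exactly at the lower bound l has violation 0 and receives the
full bonus (continuous limit), but the satisfied *count* uses the strict
condition l < d ≤ u.  Restraint totals are summed, not normalised by
restraint count, matching the maximise-the-satisfied-count reading.

## Coarse-grained chain model

The search operates on a Cα trace in internal coordinates: fixed 3.8 Å
virtual bonds, pseudo bond angles θ and pseudo torsions τ.  Cartesian
coordinates are rebuilt deterministically by sequential natural-extension
(NeRF) placement, so bond lengths are exact by construction and every move
is a change of angles only.  An ideal right-handed α-helix corresponds to
θ ≈ 90.4°, τ ≈ +50.0° (2.3 Å helix radius, 1.5 Å rise, 100°/turn).

The energy combines four terms:

| term | form | default |
| --- | --- | --- |
| steric | Σ max(0, r₀ − d)² over pairs with sequence separation ≥ 2 | weight 1.0, r₀ = 4.0 Å |
| compaction | max(0, Rg − Rg*)², Rg* = 2.2 N^0.38 Å | weight 0.5 |
| secondary-structure bias | Σ (θ − θ₀)² + wrapped (τ − τ₀)² over annotated residues | weight 0 unless annotations supplied (1.0 in the pipeline runs) |
| restraints | −w_r · Σ Lorentz bonus | w_r = 4.0 |

Only chain expansion is penalised by the compaction term; collapse is
resisted by the steric core.  The per-residue (θ₀, τ₀) preferences play the
role that fragment libraries derived from secondary-structure prediction
play in fragment-assembly methods: they inject local geometry, never
tertiary information.  Restraint weight 4 per unit of E_max makes the
restraint term dominate over the smooth background for realistic restraint
counts (≈1–2.5 per residue), which is the regime where cross-link-guided
search is reported to work.

Flexible loops and disordered termini can be *masked*: masked residues keep
only the repulsive steric term and are excluded from compaction, bias and
restraint scoring, so they are modeled but not scored.  The mask is a
user-supplied residue selection (disorder prediction is out of scope).

## Staged model-based search

The search runs in `n_stages` = 6 stages of `structures_per_stage`
trajectories each (200 by default at desk scale; the production scale of
5000 is a configuration value, not a code change).  Moves resample the
internal coordinates of one contiguous window: any window up to the whole
chain in stage 1 (coarse topology building), 9-residue windows in the
middle stages, 3-residue windows in the final refinement stage — the
coarse-to-fine schedule of fragment-assembly protocols without the fragment
database.  Proposals draw angles near the per-residue preference when one
is annotated (80% of draws, σ ≈ 0.1–0.18 rad) and otherwise from a mixture
of helix-like and extended geometry.  Acceptance is Metropolis with a
stage-geometric temperature schedule from 2.5 down to 0.4 energy units;
the spec source delegates this machinery to an external sampler, so the
schedule is this package's own choice, with defaults in `SearchConfig`.

After every stage the pool is clustered by greedy leader clustering on
selected-Cα RMSD (cutoff 4 Å), visiting conformations by increasing energy:
each joins the first cluster whose representative is within the cutoff,
else founds a new one.  Clusters are interpreted as *funnels* of the energy
landscape.  A funnel's quality is the mean energy of its five lowest-energy
members after a short greedy (downhill-only) refinement with small-window
moves; funnels whose unrefined five-best mean lies more than
`refine_margin` = 15 energy units above the best funnel keep the unrefined
estimate, since their allocation weight is negligible either way.  Sampling
effort for the next stage is drawn from a softmax over qualities,

    weight_i ∝ exp(−quality_i / T_alloc),   T_alloc = 1.0,

so better funnels (lower quality value) receive more trajectories; the
next stage starts each trajectory from a random member of the drawn
funnel.  The final result retains every conformation from every stage,
with stage, funnel and score provenance per structure.

Window resampling explores basins but rarely reaches their floors, so the
pipeline runs an optional *polish* pass between search and selection
(`polish_ensemble`): the twenty lowest-energy structures each get a
low-temperature (T = 0.1) Metropolis trajectory of small Gaussian angle
perturbations (σ = 0.05 rad, 400 moves), and the polished models are
appended to the ensemble with their provenance.  The final search stage
also mixes such polish proposals into its move set at 50%.

All stochastic steps consume one seeded generator per search, so a fixed
seed reproduces the result bit-for-bit.

## Model selection

Single scores are imperfect; the selection protocol therefore runs in two
stages: rank by a primary score, keep the best `k_filter` = 10, re-rank
those by a secondary score, and report the top structure ("first
structure") plus the best `k_report` = 5 for inspection.  Available scores:
full search energy, physics-only energy (restraint term removed), the
Lorentzian restraint bonus, the satisfied-restraint count, and arbitrary
imported per-structure score tables (the pluggable stand-in for external
statistical potentials).  The default pairing filters by energy and
re-ranks by restraint bonus (the raw Lorentz sum; the satisfied count is
exposed as an alternative).  Evaluation reports the RMSD of the first
structure and the minimum RMSD among the reported five ("best-of-five"),
which by construction is never worse.  A first structure below 6 Å is
flagged as correct topology.

## Superposition RMSD and validation analyses

RMSD uses optimal proper-rotation superposition (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`, determinant +1 only)
over a residue selection given in the compact text form `"a-b:c-d"`.
Structures are paired by residue index; at least three common residues are
required.

Three cross-link validation analyses are provided:

* **Distance versus decoy distributions** — Cα distances of identified
  links on a reference structure, against the distances of random
  chemistry-respecting pairs (NHS end at K/S/T/Y/N-terminus, separation
  filter applied).  Random pairs are a surrogate for decoy-database hits;
  real decoy hits additionally reflect the score distribution of the
  search engine, a documented approximation.
* **Site-shift robustness** — every diazirine site is re-drawn uniformly
  once within ± (W−1)/2 residues (clipped to the chain) per repetition;
  the shifted distance distribution is compared to the original by the
  absolute change of the median (effect size, Å) and a two-sample
  Kolmogorov–Smirnov p-value.  The KS test was chosen because the
  comparison is between whole distributions; the significance threshold
  defaults to p = 0.05.  Means ± sd over 100 repetitions are reported.
  Clipping is at chain bounds; peptide-bounded clipping would need peptide
  annotations, which the link-level format does not carry.
* **Helical-wheel arc** — linkage sites mapped to angles at 100°/residue;
  the smallest circular arc containing all site angles is computed from
  the largest angular gap.  An arc ≤ 180° (boundary inclusive) means the
  sites sit on one helix face, the signature of a single nearby residue
  cross-linking to the exposed face of an α-helix.

Residue numbering is taken to be 1-based in the supplied sequence; mapping
to PDB numbering is an explicit integer offset, never guessed.

## Synthetic data: what it emulates and what it does not

The generator builds ideal-geometry helix bundles (default three 12-residue
helices joined by 4-residue turns, 44 residues) in internal coordinates;
turn angles (θ = 100°, τ = −80°) were tuned once to give antiparallel
packing at ~10 Å axis separation without clashes.  Sequences scatter
K/S/T/Y at density 0.3, approximating the NHS-reactive surface density of
a typical soluble protein.

Simulated links respect SDA chemistry and a 20 Å true-link bound.  The
default density is ~2.5 links per residue (110 links on the 44-mer),
matching the reported density of high-density photo-cross-linking at a 20%
FDR.  A configurable `noise_fraction` (default 0.1) of links is drawn from
all eligible pairs with **no** distance condition — false links spread over
the full distance range, as decoy identifications do.  Site imprecision
jitters each diazirine site uniformly within an odd window (default 5,
i.e. ±2 residues).  Assigned q-values put true links in [0, 0.10] and false
links in [0.02, 0.20], so a 20% FDR cut keeps essentially everything and a
10% cut preferentially removes noise; the simulator is a data generator,
not a search-engine model.

Not emulated: solvent accessibility (eligibility is sequence- and
distance-based only), spectrum-level effects (no m/z, no fragmentation),
peptide-level detectability correlations, and real decoy score
distributions.  Passing the recovery tests therefore shows that *given*
identifications with the assumed error structure the pipeline recovers
topology; it does not validate the identification step itself.

## Problem sizes and reproducibility

Desk-scale defaults (44-residue bundles, 100–200 structures per stage,
60 moves per trajectory) keep a full six-stage search in the tens of
seconds on one CPU; these sizes are the package's chosen test scale, and
all of them scale up by configuration only.  Every random choice in the
package flows from an explicit integer seed: the simulator, the decoy
distribution, the shift analysis and the search each take their own, and
the CLI derives per-step seeds from one global seed and records them in a
run manifest.

## Known limitations

* The coarse-grained energy has no attractive packing term; helix–helix
  packing is driven entirely by restraints and compaction, so domains
  stabilised by specific side-chain packing are outside the model.
* Cα-only restraints: no Cβ or side-chain nitrogen distance definitions.
* The two-decoy-class FDR formula is a reconstruction of common practice;
  with inputs that carry only one decoy class the D/T fallback changes the
  estimate.
* Distance restraints cannot distinguish mirror-image topologies; the
  right-handed helix prior in the move set and the secondary-structure
  bias break the tie only partially at coarse resolution.
* Greedy funnel refinement is short and downhill-only; funnel qualities
  are noisy estimates, deliberately traded for speed.
* On small targets (≲ 50 residues) the 20 Å restraint band is weakly
  informative: several distinct compact arrangements can satisfy every
  restraint at the full Lorentz plateau, so the lowest-energy basins are
  near-degenerate and rank-1 selection is unstable around the 6 Å
  correct-topology threshold, while best-of-five selection is markedly
  more reliable.  The regime improves with protein size, since a fixed
  20 Å bound excludes a growing fraction of residue pairs.
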