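# Methods

`metachem` compares two labeled collections of small molecules — in the
motivating application, metabolites reachable in anaerobic vs. aerobic
metabolic networks — in structural, chemical and reaction space, and adds
enzyme-level contingency analyses. This note records the models and
procedures, the defaults and why, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Structure standardization

Input records (SMILES lines or SDF) are standardized before any analysis:

* **Largest fragment** by heavy-atom count is retained (salts and solvent
  fragments are dropped). Ties are broken by canonical-SMILES
  lexicographic order, keeping the first — an arbitrary but deterministic
  rule.
* **Neutralization** changes protonation states only: carboxylates,
  phosphates, alkoxides and similar anions gain a proton; protonated
  amines lose one. Heavy-atom bonds are never made or broken.
  Permanently charged centres (quaternary nitrogen, internal salt
  bridges) keep their charge and the metabolite is flagged
  (`residual_charge:+1` etc.).
* Records containing wildcard/query atoms (R groups, polymeric repeat
  units) are rejected with a logged reason, never silently dropped.
* Stereochemistry is preserved as given and never inferred.
* Aromaticity follows RDKit's default perception model; no alternative
  convention is configurable. This is the one documented default for an
  inherently convention-dependent step.

`standardize` is idempotent, always leaves exactly one fragment, and never
increases the heavy-atom count; these are tested properties.

## Descriptor panel

Twenty descriptors per molecule, computed from the hydrogen-complete graph
(column names are the conventional symbols):

| symbol | definition | units |
|---|---|---|
| MW | molecular weight | Da |
| AREA | solvent-accessible surface area over one conformer | Å² |
| VOL | van der Waals volume (voxelized union of spheres) | Å³ |
| AtomCount / BondCount | atoms / bonds incl. hydrogens | count |
| Carbons … Phosphorus | element counts | count |
| AlogP98 | Ghose–Crippen atom-contribution logP | — |
| PSA | topological polar surface area | Å² |
| PV | polar volume: VOL restricted to N/O/P/S and attached H | Å³ |
| Acceptor / Donor | N+O atoms / N–H+O–H hydrogens (Lipinski conventions) | count |
| Hydrophobe | maximal connected fragments of ≥3 non-polar atoms | count |
| RingCount / AromaticRings | SSSR rings / aromatic rings | count |
| RotBonds | single non-ring bonds between non-terminal heavy atoms, amide C–N excluded | count |
| Chiral | tetrahedral stereocenters, specified + unspecified | count |

Choices that deserve comment:

* **AlogP98.** The historical AlogP98 parameterization is proprietary; we
  use the open Ghose–Crippen-family atom-contribution logP (RDKit
  Crippen). Absolute parity with the proprietary value is impossible and
  not attempted: every downstream conclusion uses differences, signs and
  rankings, which are robust to the choice of contribution table.
* **Donor/Acceptor** follow the Lipinski counting conventions (acceptors
  = N+O count, donors = N–H/O–H hydrogen count), so water has acceptor 1
  and donor 2.
* **Hydrophobe** has no universal definition; ours (connected subgraphs
  of ≥3 uncharged C/halogen/thioether-S atoms with no neighbor in
  {N, O, P} or charged) is exposed in code and stable under atom
  reordering.
* **PSA** is topological (TPSA); **AREA/VOL/PV** are 3D, computed on one
  conformer from deterministic distance-geometry embedding (ETKDG, seeded)
  followed by MMFF relaxation. The probe radius for AREA defaults to
  1.4 Å. PV is computed on a 0.35 Å voxel grid: a voxel inside any atomic
  sphere counts toward VOL, and toward PV when its nearest covering atom
  is N/O/P/S or a hydrogen bound to one. Mixing a topological PSA with
  3D-derived volumes mirrors the mixed descriptor provenance that is
  common in practice; only within-column comparisons are ever made.
* **Fallback.** When 3D embedding fails (or is disabled for speed),
  AREA/VOL/PV use additive per-atom increments — a fixed fraction of each
  isolated atomic sphere's surface (25%) and volume (80%). These
  increments are crude but monotone in composition, which is all that
  difference-based analyses need; the vector is flagged.

## Scaffolds

Scaffolds are Murcko frameworks: contiguous ring systems plus the chains
linking them, with terminal substituents pruned. Pruning deletes atoms
only and never rewrites bond orders, so double bonds exocyclic to rings
(ring C=O) and double bonds inside linkers survive — cyclohexanone's
scaffold is cyclohexanone. Acyclic molecules have no scaffold; they are
counted separately and are deliberately *not* treated as a shared "empty
scaffold" between two sets, which would make any two sets trivially
overlap. A census reports distinct scaffolds, occurrence counts, and the
density (distinct scaffolds per metabolite, 3 decimals); a comparison
reports shared scaffolds, scaffolds novel to the second set, and a
prevalence ranking with canonical-SMILES tie-breaking.

## Structural similarity map

Fingerprints are hashed path-based binary fingerprints (2048 bits,
deterministic). The original analysis used a proprietary substructural
fragment dictionary; any dense substructural fingerprint supports the same
similarity geometry, and all conclusions drawn from the map are
structure-level (who clusters with whom), not bit-level. Single-atom
molecules, which have no bond paths, receive a composition-derived bit so
no fingerprint is empty.

Tanimoto similarity is TC = N_c/(N_a + N_b − N_c); two empty fingerprints
are defined to have TC = 0. Compounds with TC > 0.85 (strict) are pooled
into clusters by connected components — single linkage, so similarity
chains merge, which is the documented consequence of the pooling rule.

The 2D map is a Sammon non-linear mapping of the distances
δ_ij = 1 − TC_ij: coordinates minimize the distance-weighted fractional
error E = (Σδ)⁻¹ Σ (δ−d)²/δ using Sammon's diagonal second-order update
(step factor 0.3, halved whenever a step would increase the stress, so
accepted stress is non-increasing; 300 iterations by default).
Initialization is the first two principal components of the binary
fingerprint matrix, plus a seeded 1e-6 jitter to break exact ties.
Duplicate fingerprints are collapsed before optimization (δ = 0 pairs are
excluded from the stress sums to avoid division by zero) and placed
coincident afterward. We optimize all compounds jointly; the batch-wise
incremental projection sometimes used for very large datasets gives a
similar but path-dependent layout and is not implemented.

## Chemical space statistics

Per-descriptor comparisons report medians, means and a two-sided Welch
(unequal-variance) t-test, with a Wilcoxon rank-sum P value as a
cross-check (descriptor distributions are typically far from normal) and
a Bonferroni-adjusted column alongside the raw P values; the primary
columns remain the raw t-test P values, matching how such tables are
conventionally reported. Descriptors constant in both sets get P = 1 and
a flag.

Factor analysis extracts the first two principal components of the
descriptor **correlation** matrix (descriptors standardized to zero mean,
unit variance; constant columns dropped with a warning) and applies a
Kaiser-normalized Varimax rotation (convergence 1e-6). Per-factor
variance explained is recomputed after rotation; the total for the pair
is invariant under the orthogonal rotation (tested to 1e-9). Scores are
regression scores from the rotated loadings; each factor's sign is fixed
so its largest-|loading| descriptor loads positively. Descriptors with
|loading| > 0.85 are reported per factor. At least 3× more rows than
descriptors are required.

The early/late ("era") comparison reuses the same machinery on one set
partitioned by age labels and additionally reports the mean factor-1
score difference (early − late) with its standardized effect size; with a
class of fewer than 2 members the tests are skipped and only means are
reported.

## Reaction analysis

Reactions are plain-text equations (`R1: 2 A + B => C`, `<=>` for
reversible, flags such as `o2` after `|`). From irreversible reactions
only, members on a cofactor list (editable file; default: ATP/ADP/AMP,
NAD(P)(H), FAD(H2), CoA, phosphate, pyrophosphate, water, CO2, O2, NH3,
H+) and members with MW < 70 Da (strict, measured after standardization)
are discarded; the survivors are paired. The default pairing is the full
Cartesian product of surviving reactants × products; a "main pair" mode
(heaviest reactant × heaviest product) is available because the pairing
convention in comparable studies is rarely stated. Pair counts are always
reported so users can compare conventions.

Net changes are product-minus-substrate deltas averaged per descriptor
over the polarity-associated subset (AlogP98, PSA, PV, Acceptor, Donor).
Pathway trajectories report the AlogP98 series along an ordered metabolite
path plus the fraction of increasing steps.

Module profiles use the bipartite metabolite↔reaction graph restricted to
a module: initial reactants are member metabolites never produced within
the module; participation counts the reactions consuming a metabolite;
distance to a designated core set counts reaction nodes on the shortest
path, searched undirected by default (reachability in metabolic maps is
conventionally discussed undirected; a directed mode following edge
direction toward the core is available). Metabolites that cannot reach
the core are excluded from the mean with a count.

## Enzyme profiles

Cofactor usage is compared per cofactor with a 2×2 chi-square
(uses/does-not-use × set) without continuity correction (a corrected mode
is available); when any expected cell is below 1 the test falls back to
Fisher's exact test and the row is flagged. Significance tiers are
P < 0.01 and P < 0.05. Cofactor categories are non-exclusive: an enzyme
counts once per cofactor it uses, so category counts may sum above the
enzyme totals. Catalytic-residue compositions are per-residue frequencies
(summing to 1 per set) compared with two-sided two-proportion z-tests —
statistically near-equivalent to per-residue 2×2 chi-squares, which is
why one of the two was chosen and documented rather than both
implemented. EC-class frequencies are a normalized 6-bin table with
out-of-range labels rejected and logged.

## Synthetic-data generator

The generator emulates the statistical structure of the motivating study
so that every stage is testable without downloads:

* **Metabolite sets** come from a scaffold-plus-decoration grammar. A
  pool of >500 distinct ring scaffolds (single rings, fused pairs, and
  ring–linker–ring combinations, including unsaturated linkers) is
  partitioned into shared / A-only / B-only groups; every designated
  scaffold is guaranteed to appear in its set(s), so a census comparison
  recovers the configured shared/novel counts exactly. Decorations are
  terminal substituents drawn from polar (–OH, –NH2, –CH2OH, –COOH,
  –CONH2) and non-polar (alkyls, –Cl) pools; the polarity shift maps to
  the sets' polar/non-polar decoration probabilities through rough
  per-substituent AlogP98 effects, and the rigidity shift maps to the
  sets' ring-count category distributions (error if the requested shift
  exceeds what the pool supports). Default condition: 1,174 vs 520
  molecules, 34 shared + 131 B-only scaffolds, mean AlogP98 gap ≈ 2.2 and
  mean ring-count gap ≈ 1.2 — the contrasts of the motivating comparison.
  A truth ledger records each molecule's scaffold and decoration counts.
* **Reaction chains**: an anaerobic-style chain starts from a
  polyhydroxylated ring system and swaps one hydroxyl for a methyl per
  step (PSA falls, AlogP98 rises); an aerobic-style chain starts from a
  long alkylbenzene and hydroxylates one chain carbon per
  oxygen-dependent step (PSA rises, AlogP98 falls). Cofactor species are
  injected into the equations and filtered out downstream. Per-step true
  deltas are recorded.
* **Enzyme annotations**: per-enzyme independent Bernoulli draws per
  cofactor (defaults follow the published usage proportions for 154 vs
  121 oxidoreductases), multinomial residue draws per catalytic site
  (453 vs 257 sites × 3 residues; a polarity bias boosts Asp/Glu/Lys/Arg
  in set A and Trp/Ile in set B), and multinomial EC classes.

All randomness flows through one seeded generator; the same seed
reproduces every output byte for byte.

What the generator does **not** emulate: chemically realistic enzymatic
transformations, thermodynamics, real scaffold prevalence distributions,
correlated descriptor noise, or the network topology of genome-scale
metabolism. Passing tests therefore demonstrate that the pipeline's
arithmetic, bookkeeping and statistics are correct under controlled
conditions — not that any biological conclusion transfers to real data.

## Problem sizes used in the checks

The automated checks run at desk scale: 200-molecule scaffold panels,
50-point Sammon recoveries, n = 1000 factor-analysis recoveries, 100
replicates for calibration (60 + 60 molecules and 80 + 80 enzymes per
replicate) and power (154 vs 121 enzymes, the study's actual enzyme
sample sizes). The headline dataset of the motivating study is not
redistributable, so dataset-scale quantities (full censuses, Table-scale
medians) are exercised on synthetic data and on the published summary
counts used as inputs.

## Known limitations

* AlogP98, Hydrophobe and the 3D surface/volume values are not
  numerically comparable to proprietary implementations; only signs,
  differences and rankings should be interpreted.
* The Sammon stress surface is non-convex; different seeds give different
  (reflected/rotated) layouts with similar stress.
* Single-conformer AREA/VOL/PV ignore conformational flexibility.
* The neutralizer handles common ionizable groups, not exotic charge
  states; residual charges are flagged rather than fixed.
* Tautomers are not canonicalized; two tautomeric inputs may count as
  different structures and scaffolds.
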