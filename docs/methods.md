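# Methods

## The model

`pcndetect` treats primary-care registration as a bipartite system:
patients live in small neighbourhoods (LSOAs) and register with
practices, and a "natural" community of practices is a set whose members
draw patients from the same neighbourhoods. The pipeline projects the
LSOA–practice registration matrix onto a practice–practice cosine
similarity network, sparsifies it, partitions it by Markov stability at
many time scales, and keeps only partitions whose communities make
geographic sense.

### Deduplication

Within the study window a patient may appear under several
(LSOA, practice) combinations — moves, re-registrations, or recording
noise. The combination with the highest record frequency is kept;
frequency ties go to the combination with the most recent record date. A
simultaneous frequency-and-date tie is resolved to the lexicographically
smallest (practice id, LSOA id) pair: such ties carry no information, and
a deterministic rule keeps the whole pipeline reproducible. Practices
with fewer than 100 unique patients are excluded, and their patients are
removed with them rather than reassigned — the patients' true
registrations are unknown, and imputing them would manufacture signal.

### Market concentration

For LSOA *i* with practice registration shares *s_ij*,
HHI_i = Σ_j s_ij² and EMS_i = 1/HHI_i. EMS is the number of practices
that would serve the LSOA if all had equal shares, a direct measure of
how contested the local market is. The same statistic is reused at PCN
level (PCN groups, plus the pool of unassigned practices as one residual
unit, as the providers).

### Similarity and sparsification

Practice profiles are the registration-matrix columns normalised to sum
to one; cosine similarity is invariant to that normalisation, so raw
counts give the identical matrix. (The registration matrix can instead
be row-normalised first — per-LSOA registration probabilities — via
`gp_profiles(mode="lsoa")`; the two conventions are not equivalent, and
the per-practice profile is the documented default because it makes each
node's vector a distribution over its own catchment.)

The dense similarity matrix is converted to distances d = 1 − s and
sparsened with a relaxed minimum spanning tree. The precise keep rule
implemented is

    keep (A,B)  ⇔  d_AB ≤ mlink_AB + (dNN_A + dNN_B) / γ

where mlink is the minimax path weight (maximum edge on the MST path —
identical for every MST, so tie-breaking in tree construction cannot
change it) and dNN is the nearest-neighbour distance. RMST variants
differ in how the local-scale term enters; dividing by γ was chosen so
that a larger γ prunes harder, matching the reading of γ as a pruning
strength scanned upward. A multiplicative variant (×γ, opposite
direction) is available behind `rmst_variant="multiplicative"`. Equality
keeps the edge, which makes the γ → ∞ limit exactly the MST plus edges
tying their minimax path. All MST edges are always retained, so the
output is structurally connected; edges whose endpoints share no LSOA
support carry similarity 0 and contribute nothing to the random walk.

### Markov stability

On the weighted graph with adjacency A, degree k and total weight 2m,
the continuous-time random walk has M = D⁻¹A and stationary distribution
π = k/2m. Partition quality at Markov time t is

    r(t, H) = Σ_c Σ_{i,j∈c} R(t)_ij,
    R(t)    = Π exp(t(M − I)) − ππᵀ

— the probability that a walk at stationarity is found in its starting
community after time t, minus the chance level. At t → 0 all
off-diagonal entries of R are negative, so the finest partition is
optimal; as t grows the walk explores further and coarser partitions
win. The full matrix exponential is used by default (dense networks of
~10³ nodes are tractable); `stability_method="linearised"` replaces the
exponential with its first-order expansion, which at t = 1 reduces
exactly to Newman–Girvan modularity (verified against igraph in the test
suite). The normalised-Laplacian continuous-time flavour is the
documented default; combinatorial-Laplacian stability is not
implemented.

r(t, H) is maximised by Louvain iterations run directly on the fixed
matrix R(t): greedy single-node moves (sweep order shuffled per seed)
alternating with aggregation that sums matrix blocks, so the quality of
the aggregated problem equals r on the original matrix exactly and no
exponential is recomputed. Each (γ, t) model is optimised
`runs_per_model` times and the most common canonical partition is kept
(multiplicity ties: higher mean r, then lexicographically smallest
labelling). The study-scale default is 500 runs; tests and the bundled
acceptance run use 20, which on the synthetic city is already far past
the point where the consensus stabilises.

Seeding: per-run generators derive from
`SeedSequence(master_seed, spawn_key=(γ-index, t-index, run))`, so any
single model can be recomputed without replaying the grid.

### Geographic validation and selection

Per candidate community, in order:

1. **Spatial outliers** — members whose median straight-line distance to
   co-members exceeds 4× the community-wide median pairwise distance are
   removed. Single pass: every member is judged against the one original
   median, because the criterion is defined once per community, not
   iterated.
2. **Size** — communities keep 3–20 practices after outlier removal.
3. **Containment** — the convex hull of member coordinates is drawn, and
   the community is excluded when more than 25% of the practices inside
   the hull (members + foreigners; boundary counts as inside) are
   foreign. The denominator "all practices inside the hull" was chosen
   because it makes the threshold a spatial-mixing fraction; counting
   against community size alone is available by computing
   `hull_containment` directly. Degenerate collinear hulls are used
   as-is and logged.

The score of a model is the number of practices in valid communities;
the grid optimum maximises it, with exact ties resolved to the smallest
γ, then the smallest t (finer partitions are preferred when the data
cannot distinguish). The Markov-time grid is log-spaced by default since
it spans two decades (0.01–1).

### Assembly

Valid communities become PCNs numbered in order of appearance. Each LSOA
goes to the PCN with the most of its patients; ties go to the smallest
PCN id, and the unassigned-practice pool loses all ties but captures
LSOAs for which it is the strict modal provider (these are reported
separately, never forced into a PCN). Coverage, list-size and CCG-span
statistics follow directly; all quantiles are plain order statistics.

## The synthetic city

The generator emulates the post-extraction registration table of a dense
urban system. k community centres sit on a jittered grid 30 length-units
apart; LSOA centroids and practices scatter around their centre with
standard deviation 5. A patient in LSOA *i* registers with practice *j*
with probability ∝ exp(−d_ij/λ) × (1 if same planted community else ε).

Defaults, chosen once as the package's study conditions:

| parameter | default | why |
|---|---|---|
| n_lsoa / n_gp / k | 300 / 60 / 6 | ~10 practices and ~50 LSOAs per community, the scale of the real PCN size window |
| decay length λ | 20 | four times the within-community scatter: practices in a neighbourhood have heavily overlapping catchments, the defining regime of an urban registration market (median LSOA EMS ≈ 9–10 in the default city). Short decay lengths spatially sort catchments *within* a community, which is a different (suburban) system: profile splits of a community then look spatially clean and the containment filter cannot reject them |
| leakage ε | 0.05 | a few percent of registrations cross community lines; ε = 0 is the exact-recovery limit used by the tests |
| patients per LSOA | 100 | keeps typical practices (~500 patients) comfortably above the 100-patient exclusion, mirroring the study population where the exclusion trims only stragglers |
| dup_rate | 0.1 | fraction of patients carrying a conflicting record; half outvoted (frequency arm), half date-dominated (recency arm), so both deduplication rules are exercised |

Duplicate records are strictly dominated by the true pair by
construction, so the planted truth is exactly recoverable — the
deduplication tests are exact, not statistical. The generator does not
model demographic structure, digital-first practices with no meaningful
geography, temporal churn, or boundary effects at the city edge; passing
the planted-recovery tests therefore demonstrates the machinery is
correct and self-consistent, not that real registration data is as
cleanly separable. CCG membership is set equal to the planted community,
giving the CCG-span statistics a known truth.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the pipeline on the
default city with a reduced grid — 5 pruning parameters × 10 Markov
times × 20 Louvain runs — which completes in seconds while still
recovering the planted partition exactly at ε = 0 and near-exactly at
ε = 0.05. The study-scale grid (40 × 400 × 500) is the config default
for real analyses.

Louvain move gains use a 1e-12 tolerance; EMS·HHI reciprocity holds to
1e-12; stability matrices are explicitly symmetrised against rounding;
canonical partition labels are assigned by first appearance so
relabelled runs compare equal. A model failure at one grid point is
logged and scored 0 rather than aborting the scan. Metrics are rounded
to 10 decimal places before JSON serialisation so identical reruns are
byte-identical.

## Known limitations

- The convex hull is a coarse footprint; a concave catchment wrapping
  around another community can evade the containment filter.
- The score ties between a correct partition and some over-merged or
  over-split variants whenever all variants pass the filters; the
  (smaller γ, smaller t) tie-break then decides, favouring the finer
  model.
- With leakage the similarity graph is fully connected and zero-weight
  edges never arise; in the sealed ε = 0 limit cross-community edges
  carry weight 0 and the random walk decomposes, which the operators
  handle (self-loops for isolated nodes) but which makes the "connected
  graph" reading of stability nominal.
- Coordinates are planar Euclidean; no geodesy. Real postcodes should be
  projected (e.g. to OSGB) before use.
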