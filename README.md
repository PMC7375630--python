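# pcndetect

Data-driven discovery of Primary Care Networks (PCNs) — groupings of
neighbouring general practices — from patient registration patterns.

English primary care is organised into GP practices whose patients come
from small census neighbourhoods (LSOAs, ~1,800 residents each). Policy
asks practices to band together into PCNs that serve "natural"
communities, but in dense cities patients routinely register far from
home and practice catchments overlap heavily, so drawing those
communities by eye is unreliable. `pcndetect` finds them from the data:
given a table of patient registrations (patient, LSOA of residence,
registered practice, record date), it builds a practice similarity
network and partitions it into geographically coherent communities, then
assigns each LSOA to a PCN and reports how well the catchments cover
their populations. A synthetic-city generator with planted communities
makes the whole pipeline testable without access to restricted
patient-level data.

## Method

1. **Deduplication** — a patient seen under several (LSOA, practice)
   combinations keeps the most frequent one; ties go to the most recent
   record. Practices with fewer than 100 patients are excluded.
2. **Market concentration** — for LSOA *i* with practice shares
   *s<sub>ij</sub>*, the Herfindahl–Hirschman index is
   HHI<sub>i</sub> = Σ<sub>j</sub> s<sub>ij</sub>², and the equivalent
   market size EMS<sub>i</sub> = 1/HHI<sub>i</sub> is the effective
   number of practices serving the LSOA.
3. **Similarity network** — each practice is a distribution over LSOAs
   of residence; edges between practices *A*, *B* carry the cosine
   similarity Σ<sub>i</sub>A<sub>i</sub>B<sub>i</sub> /
   (‖A‖‖B‖).
4. **Sparsification** — the dense network is reduced with a relaxed
   minimum spanning tree: an edge survives if its length does not exceed
   the max-link (minimax) path between its endpoints plus a local-scale
   relaxation (d<sup>NN</sup><sub>A</sub>+d<sup>NN</sup><sub>B</sub>)/γ.
5. **Markov-stability community detection** — communities maximise the
   probability that a random walk stays within its starting community
   over a Markov time *t*, r(t,H) = Σ<sub>c</sub>Σ<sub>i,j∈c</sub>
   [Π e<sup>t(M−I)</sup> − ππᵀ]<sub>ij</sub>, optimised by repeated
   seeded Louvain runs with a consensus (most common partition) step.
6. **Geographic validation and model selection** — over a grid of
   (γ, t) models, communities are screened for spatial outliers
   (median co-member distance > 4× the community median), size (3–20
   practices) and convex-hull containment (≤ 25% foreign practices
   inside the hull); the model whose valid communities contain the most
   practices wins.
7. **Assembly** — LSOAs are assigned to the PCN holding most of their
   patients; coverage, list sizes, CCG span and PCN-level EMS are
   reported.

## Worked example

```python
from pcndetect import PipelineConfig, run_pipeline

config = PipelineConfig(gamma_num=5, t_num=10, runs_per_model=20, master_seed=1)
metrics = run_pipeline(config, "out/")
print(metrics["n_pcns"], metrics["planted_ari"], metrics["pcn_coverage_median"])
```

This simulates the default city (300 LSOAs, 60 practices in 6 planted
communities, 5% cross-community leakage, 30,000 patients), scans the
reduced 5 × 10 model grid and prints

```
6 1.0 94.4208486332
```

— the pipeline found 6 PCNs that match the planted communities exactly
(adjusted Rand index 1.0), and the median PCN keeps 94.4% of the patients
living in its catchment registered inside it (the missing patients are the
deliberate cross-community leakage). The same run reports a median LSOA
equivalent market size of 10.35 practices and an optimal model at
γ = 2.1, t = 0.359. `out/` receives every intermediate artifact
(registration matrix, similarity edge list, per-model grid results,
membership, assignment and summary tables, `metrics.json`, and a
provenance manifest).

The same pipeline is available from a shell:

```bash
pcndetect -v run --seed 1 --gamma-grid 2.1 6.0 5 --t-grid 0.01 1.0 10 \
    --runs 20 --out-dir out/
pcndetect report --out-dir out/
```

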