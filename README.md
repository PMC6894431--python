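# oxynet

Individual-based analysis of host–endosymbiont bipartite networks,
built around the interaction between spur-thighed tortoises
(*Testudo graeca*) and the pinworm-like oxyurid nematodes
(Pharyngodonidae) of their hindguts.  The same gut nematode community
can act as mutualist, commensal or parasite; this package implements the
statistical machinery needed to ask how that interaction spectrum shifts
across landscapes with different levels of habitat loss:

- **Weighted bipartite network metrics.**  For an adjacency matrix *A*
  with *a<sub>ij</sub>* = adult worms of species *i* in tortoise *j*:
  nestedness *WNODF* (weighted overlap and decreasing fill, 0–100),
  connectance *C* (realized links / possible links), interaction
  diversity *ID* (Shannon entropy of link weights, nats), the
  network-level specialization index *H₂′* ∈ [0, 1], and per-host
  species-degree and Blüthgen's *d′* (standardized Kullback–Leibler
  divergence of a host's partner spectrum from partner availability).
- **Null-model significance.**  Monte-Carlo test of *WNODF* against a
  degree-proportional null in which each cell occurs with probability
  *P<sub>ij</sub>* = (*k<sub>i</sub>*/*S* + *k<sub>j</sub>*/*R*)/2 — the
  average of the row and column fill proportions — with permuted
  observed weights on the filled cells; upper-tail, add-one-corrected p.
- **Rank/abundance evenness.**  Dominance curves (log₁₀ relative
  abundance vs. rank) per habitat and a sequential ANCOVA whose
  habitat × rank interaction tests whether community evenness differs
  among habitats.
- **Growth and association models.**  Per-individual von Bertalanffy
  growth-rate scores *k* = −(1/t)·ln[(L<sub>∞</sub> − L)/(L<sub>∞</sub> − L₀)]
  from carapace length and ring-estimated age; habitat-stratified
  ANCOVAs of *k* on infestation (richness or worm abundance) with
  per-habitat slope-sign classification; per-host Poisson GLMs of
  species-degree on body traits with deviance χ² tests and
  overdispersion rescaling.  The linear/GLM engine (treatment-coded OLS,
  sequential Type-I F tables, Poisson IRLS) is self-contained.
- **A synthetic-data generator** producing study-shaped datasets
  (3 habitats with 26/20/20 tortoises, a 14-species pool, counts from 0
  to the low thousands, nested infection structure, habitat-dependent
  growth–infestation associations) with known ground truth, so the whole
  pipeline is testable without any field data.

Intended users: community ecologists and parasitologists analysing
individual-based host–symbiont count matrices, and anyone needing a
scriptable WNODF / *H₂′* / *d′* implementation with a calibrated null
model.

## Worked example

Generate a synthetic study and analyse its low-habitat-loss network:

```bash
$ oxynet simulate --seed 7 --out demo
wrote 66 hosts and 3 matrices to demo

$ oxynet metrics demo/matrix_low.csv --habitat low
{
  "wnodf": 57.038239538239544,
  "connectance": 0.2932692307692308,
  "interaction_diversity": 3.626285897367108,
  "h2prime": 0.3885415850142517,
  "n_hosts": 16,
  "n_species": 13,
  "n_links": 61
}

$ oxynet nulltest demo/matrix_low.csv --replicates 1000 --seed 7
{
  "observed_wnodf": 57.038239538239544,
  "null_mean": 26.66661515301775,
  "null_sd": 3.9725242428755827,
  "z": 7.6454220360494896,
  "p_value": 0.000999000999000999,
  ...
}
```

Reading: 16 of the 26 sampled tortoises carried adult worms and enter
the network; 61 of the 13 × 16 possible species–host links are realized
(*C* ≈ 0.29).  The observed nestedness (WNODF ≈ 57) sits ~7.6 null
standard deviations above the degree-proportional null mean (≈ 27), so
the infection structure is significantly nested (p ≈ 0.001, the add-one
floor at 1000 replicates): species infecting few tortoises occur in the
tortoises hosting the most species.  The same stages are available from
Python (`oxynet.simulate_study`, `oxynet.network_metrics`,
`oxynet.nestedness_test`, …), and `oxynet run config.yaml` orchestrates
the full pipeline (networks → null tests → rank/abundance → trait
summaries → ANCOVAs → GLMs) into JSON reports.

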