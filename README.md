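# helixcg

Helix-centered coarse-grain RNA 3D modelling and ensemble sampling.

Given a pseudoknot-free secondary structure, `helixcg` decomposes it
into typed elements — stems, hairpins, interior loops, multiloop
segments and the 5'/3' unpaired regions — and represents each stem as a
cylinder `(a_s, a_e)` with end twist vectors `(t_s, t_e)`.  Tertiary
structures are assembled by sampling six inter-helical placement
parameters `(r, u, v, u_p, v_p, t)` per connecting element from
bucketed fragment statistics, and a Metropolis–Hastings chain explores
the ensemble under an energy of the form

    E(x) = −c · log( p_target(x) / p_reference(x) )

for coarse-grain measures *x* (radius of gyration over stem virtual
residues, expected A-minor interaction counts per loop, hairpin
nearest-neighbour distances), plus hard clash and junction-closure
penalties.  The reference distribution is re-estimated from the
chain's own samples every tenth step, so the sampled ensemble is
steered toward the *distribution* of native-like measures rather than
toward a single optimum.  The intended users are structural
bioinformaticians who want fast, ensemble-level exploration of global
helix arrangements — not all-atom accuracy.

## Worked example

Sampling a two-hairpin structure toward a compacted target radius of
gyration, with the package's synthetic fragment statistics:

```python
import numpy as np
from helixcg.energy import (EnergyFunction, EnergyTerm,
                            MeasureDistribution, radius_of_gyration)
from helixcg.model_builder import build_model
from helixcg.proposal_stats import SynthConfig, synthesize_stats
from helixcg.sampler import js_divergence, run_simulation
from helixcg.ss_graph import build_skeleton_graph, parse_dotbracket

table = synthesize_stats(SynthConfig(), np.random.default_rng(0))
graph = build_skeleton_graph(parse_dotbracket("((((....))))...((((....))))"))

rng = np.random.default_rng(1)
proposal = np.array(
    [radius_of_gyration(build_model(graph, table, rng)) for _ in range(500)]
)
target = np.random.default_rng(2).normal(
    proposal.mean() - proposal.std(), 0.75 * proposal.std(), 1000
)

dist = MeasureDistribution("rog", target, proposal[:200])
energy = EnergyFunction(
    terms=[EnergyTerm("rog", radius_of_gyration, dist)], use_constraints=False
)
result = run_simulation(graph, table, energy, n_iter=10_000, seed=3)
sampled = result.measure_series("rog")
print(f"proposal ROG: {proposal.mean():.2f} +/- {proposal.std():.2f} A")
print(f"target   ROG: {target.mean():.2f} +/- {target.std():.2f} A")
print(f"sampled  ROG: {sampled.mean():.2f} +/- {sampled.std():.2f} A")
print(f"JS(sampled, target)  = {js_divergence(sampled, target):.3f}")
print(f"JS(proposal, target) = {js_divergence(proposal, target):.3f}")
print(f"acceptance rate: {result.acceptance_rate:.1%}")
```

prints

```
proposal ROG: 7.19 +/- 0.55 A
target   ROG: 6.63 +/- 0.42 A
sampled  ROG: 6.88 +/- 0.47 A
JS(sampled, target)  = 0.073
JS(proposal, target) = 0.171
acceptance rate: 90.9%
```

Direct sampling of the proposal statistics gives structures around
7.2 Å radius of gyration; the adaptive reference-ratio term pulls the
sampled ensemble most of the way to the shifted 6.6 Å target, cutting
the Jensen–Shannon divergence to the target by more than half while
still accepting ~91% of proposals.

## Command line

```
helixcg fold STRUCTURE [--stats FILE] [--corpus FILE] [--iterations N] [--seed N]
helixcg thread PDB PAIRS [--out FILE]
helixcg stats synth|extract ...
helixcg eval rmsd A.cg B.cg
helixcg diag js TRAJECTORY CORPUS [--measure NAME]
```

`fold` samples models for a dot-bracket file (FASTA-style header and
sequence lines allowed) and writes the best model in the coarse-grain
text format plus a TSV trajectory; `thread` fits the cylinder model
onto an all-atom PDB structure given a two-column canonical base-pair
list; `stats synth`/`stats extract` create or mine placement
statistics; `eval rmsd` superposes the stem virtual residues of two
coarse-grain files; `diag js` reports the running Jensen–Shannon
convergence diagnostic.

File formats (stats tables, coarse-grain models, measure corpora,
trajectories) are line-oriented text; see `docs/methods.md` for the
model description and the docstrings in `helixcg.proposal_stats` /
`helixcg.io_eval` for the grammars.

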