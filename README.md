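# cardsflux

Analysis machinery for dissecting slow ligand-release mechanisms in
proteins — the kind of question posed by GDP release from a Gα subunit,
where a GPCR-binding interface and a nucleotide-binding site ~30 Å apart
must communicate allosterically, and the release event itself is far too
slow for brute-force simulation. `cardsflux` implements the full analysis
stack for such problems as a reusable, tested Python library:

* **Dihedral correlation analysis (CARDS).** Every backbone φ/ψ dihedral is
  discretized into two rotameric states (cis/trans) and every side-chain χ
  into three (gauche+, trans, gauche−); each dihedral additionally carries a
  binary *dynamical* state (stably ordered vs. rapidly hopping, i.e.
  disordered). Communication between dihedrals X and Y is the holistic sum
  of four normalized mutual-information channels,

  `I_H(X,Y) = Ī_ss + Ī_sd + Ī_ds + Ī_dd`,

  each channel being the plug-in MI divided by its channel capacity
  `log2(min |X|, |Y|)`. Residue-level aggregation, target-site
  communication profiles with bootstrap uncertainties, iterative
  allosteric-network tracing from a seed site to a sink, global
  communication (hub detection), and Shannon-entropy disorder maps
  (`H = −Σ p log2 p`, normalized per residue) are built on top.

* **Markov state models.** Hybrid k-centers/k-medoids geometric clustering,
  protein × ligand product states, sliding-window count matrices at a lag
  time τ, a detailed-balance (symmetrized-count) transition-matrix
  estimator with ergodic trimming, and implied-timescale validation
  `t_i = −τ / ln λ_i(τ)`.

* **Transition path theory.** Forward committors q⁺ from the linear
  boundary-value problem, reactive fluxes
  `f_ij = π_i q⁻_i T_ij q⁺_j`, net fluxes, the k highest-flux
  (maximum-bottleneck) release pathways by iterative widest-path
  decomposition, and the rate-limiting step — the minimum-flux step of
  those pathways, with a consensus rule across paths.

* **Metadynamics + string method.** Overdamped Langevin dynamics on
  analytic collective-variable potentials with history-dependent Gaussian
  bias deposition (`V_G → −F(S)` as t → ∞), free-energy-surface
  reconstruction with tail averaging, a zero-temperature string method for
  minimum free-energy paths, and seeding of follow-up simulations along the
  path.

* **Synthetic ground truths.** Because release-scale molecular datasets are
  hundreds of gigabytes and not redistributable, every input is generated
  synthetically with *planted* structure: coupled-rotamer ensembles with a
  known allosteric graph, bound→unbound Markov chains with a designed
  bottleneck edge, and particle trajectories on analytic potentials. All
  generators are bit-reproducible for a fixed seed, so every claim the
  package makes is checked against an independent oracle or a planted
  truth.

## Worked example

Plant a communication chain `0 → 1 → 2 → 3` among 10 residues, recover it,
then find the rate-limiting step of a toy unbinding chain with a designed
bottleneck between states 3 and 4:

```python
import numpy as np
from cardsflux import cards, featurize, msm, synthetic, tpt

spec = synthetic.PlantedNetworkSpec(
    n_residues=10, dihedrals_per_residue=2,
    edges=[(0, 1, 0.7), (1, 2, 0.7), (2, 3, 0.7)],
    frame_count=100_000, seed=42)
states = featurize.assign_rotamers(synthetic.gen_coupled_rotamers(spec))

matrix = cards.holistic_matrix(states)
res_ids, comm = cards.residue_matrix(matrix)
net = cards.trace_network(states, seed_site=[0], sink_site=[3], seed=0)
print("trace frontiers:", [f.tolist() for f in net.frontiers])

toy = synthetic.ToyUnbindingSpec(n_intermediate_states=5, bottleneck_edge=3, seed=0)
_, trajs = synthetic.gen_unbinding_chain(toy, n_steps=1_000_000)
model = msm.transition_matrix(trajs, lag=1)
fluxnet = tpt.flux_network(model, [0], [6])
consensus, _ = tpt.rate_limiting_step(tpt.top_paths(fluxnet, k=10))
print("committors:", np.round(fluxnet.committor, 3))
print("rate-limiting step:", consensus)
```

Output:

```
trace frontiers: [[1], [2], [3]]
committors: [0.    0.009 0.018 0.028 0.98  0.99  1.   ]
rate-limiting step: (3, 4)
```

The three strongest residue pairs by holistic communication are the three
planted edges (I_H sums ≈ 1.74 each, vs. 1.22 for the strongest transitive
pair), the iterative trace recruits the chain in order, and the committor
jump from 0.028 to 0.98 across the designed low-rate edge marks it as the
release bottleneck — exactly the signature used to locate a rate-limiting
step in a real release network.

A command-line interface mirrors the stages (`cardsflux simulate / featurize
/ cards / msm / tpt / metad / pipeline / validate`); `cardsflux pipeline
--config cfg.yaml` runs synthetic → correlation → MSM → TPT end to end and
writes a manifest with per-stage checksums.

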