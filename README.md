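# tns — critical nodes in temporal networks

`tns` identifies *critical nodes* (influential spreaders, potential
super-spreaders) in temporal networks: networks whose edges exist only at
certain times, represented as a sequence of `L` snapshot graphs
`G_1 … G_L` on a shared set of `N` nodes. Which node, if it starts an
epidemic or a rumour, infects the largest part of the network? The package
is aimed at researchers in network epidemiology and computational social
science who work with timestamped contact data (face-to-face proximity
logs, message streams, KONECT-style edge lists) or with synthetic temporal
graphs.

The ground truth of influence is the **SIR spreading model** run on the
snapshots: an infectious node infects each susceptible neighbour in the
current snapshot with probability β, then recovers (recovery probability
μ = 1, i.e. one infectious snapshot per node). The *infected scale*
`N_v(L)` — the ever-infected count when the epidemic is seeded at `v` — is
estimated by Monte-Carlo averaging and defines the reference ranking.

## The MLI ranking method

**MLI** (machine-learning index) turns node ranking into regression:

1. **Neighbourhood embedding.** For each node `v`, select `D` slots —
   `v` itself, then its aggregated-graph neighbours breadth-first (1-hop
   before 2-hop, larger temporal degree first) — and build a `D×D`
   feature matrix `M` with decay weights `w_t = α^(t−1)` over snapshots:

   - `M[i][j] = Σ_t w_t · 1[(s_i, s_j) ∈ E_t]` (off-diagonal),
   - `M[i][i] = Σ_t w_t · deg_t(s_i)` (diagonal).

   The decay points forward in time because with μ = 1 an outbreak seeded
   at snapshot 1 is decided by the earliest snapshots. At `α = 1` the
   matrix reduces to a plain aggregated adjacency patch.

2. **CNN regression.** A small convolutional network — conv 5×5 (1→16
   channels) + 2×2 max-pool, conv 5×5 (16→32) + 2×2 max-pool, fully
   connected `32·(D/4)² → 1`, ReLU activations, squared-error loss — is
   trained with Adam to predict each node's simulated infected scale (at
   training infection rate β_t) from its feature matrix.

3. **Ranking.** Any network's nodes are embedded the same way and ranked
   by the trained network's score. A model trained once on a synthetic
   temporal scale-free network transfers to other networks.

Defaults follow `D = 8`, `α = 0.2`, `β_t = 0.1`.

For comparison the package implements five benchmark temporal
centralities — temporal closeness (TC), temporal betweenness (TB, counted
over foremost time-respecting paths with waiting), temporal k-shell (TK),
temporal degree deviation (TDD) and temporal dynamics-sensitive centrality
(TDC) — and the evaluation protocol: Kendall tau-b between a method's
scores and the SIR truth, and the hitting rate `HR = |C ∩ R| / |R|` of the
true top-10% spreaders.

## Worked example

```python
from tns import (generate_temporal_ba, TrainingConfig, fit_mli, score_nodes,
                 ground_truth, kendall_tau, hitting_rate, tdd)

train_net = generate_temporal_ba(300, 1, 10, seed=1)   # 10 BA snapshots
test_net  = generate_temporal_ba(300, 1, 10, seed=2)   # independent instance

model, history = fit_mli(train_net, TrainingConfig(beta_t=0.1, seed=1))
print(f"training loss: {history[0]:.3f} -> {history[-1]:.4f}")

scores = score_nodes(model, test_net)                  # D=8, alpha=0.2
truth  = ground_truth(test_net, beta=0.1, runs=500, seed=1)
print(f"MLI  tau={kendall_tau(scores, truth):.3f}  "
      f"HR@10%={hitting_rate(scores, truth, 0.1):.3f}")
base = tdd(test_net)
print(f"TDD  tau={kendall_tau(base, truth):.3f}  "
      f"HR@10%={hitting_rate(base, truth, 0.1):.3f}")
print("top-5 predicted spreaders:", scores.ranking()[:5].tolist())
print("top-5 true spreaders:     ", truth.ranking()[:5].tolist())
```

prints

```
training loss: 0.945 -> 0.0519
MLI  tau=0.457  HR@10%=0.800
TDD  tau=0.408  HR@10%=0.367
top-5 predicted spreaders: [2, 3, 5, 0, 17]
top-5 true spreaders:      [2, 0, 3, 17, 5]
```

The trained model, applied to a network it has never seen, correlates with
the simulated influence ranking (tau 0.46) more strongly than the
degree-deviation baseline and recovers 80% of the true top-10%
spreaders — including four of the top five.

The same pipeline is available from the shell:

```bash
tns generate -n 300 -l 10 --seed 1 train.tsv
tns train train.tsv model.npz
tns generate -n 300 -l 10 --seed 2 test.tsv
tns rank --model model.npz test.tsv scores.csv
tns evaluate --methods mli,tc,tk,tdd,tdc test.tsv results.csv
```

(`tns bin` converts a raw timestamped edge stream into snapshots; `tns
sir`, `tns centrality` and `tns grid` expose the remaining pieces.)

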