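# locpath

Localization-aware reconstruction of cell signaling pathways from weighted
protein–protein interaction (PPI) networks.

## The problem

Given a directed interactome G = (V, E) with edge confidences
w(u,v) ∈ (0, 1], a set R of membrane receptors and a set T of
transcriptional regulators (TRs) for a pathway of interest, a *pathway
reconstruction* is the ranked list of the k shortest loopless
receptor-to-TR paths 𝒫 = ⟨P₁, …, P_k⟩ under the negative-log transform of
the edge weights.  Each path Pᵢ = (v₁, …, v_m) is ranked by its
*reconstruction score* rᵢ = ∏ w(vⱼ, vⱼ₊₁), with rᵢ ≥ rᵢ₊₁.

Two things go wrong in practice.  First, interactome confidence scores are
coarse — two or three distinct weight values often cover most edges — so
large runs of paths share exactly the same score and their relative order
is arbitrary.  Second, a path can be biophysically plausible yet
biologically impossible: signal transduction flows from the extracellular
membrane through the cytosol into the nucleus, and a path that jumps from
the membrane straight into the nucleus, or doubles back, is misleading.

`locpath` addresses both with protein subcellular localization scores
ℓ_v^c ∈ [0, 1] (the likelihood protein v resides in compartment c, as
provided by resources such as ComPPI):

1. **Filter** — edges whose interaction score (the probability the
   interaction occurs anywhere in the cell) is zero are removed before
   reconstruction.
2. **Re-rank** — with localization costs ℓ̄_v^c = −log ℓ_v^c, a dynamic
   program computes each path's *signaling score*: the minimum total cost
   of assigning compartments to its nodes so the assignment starts at the
   membrane (*ExtMem*), ends in the *Nucleus*, and advances only forward
   along ExtMem → Cytosol → Nucleus.  Signaling may advance either through
   a compartment shared by the interacting pair or by one protein
   traversing between compartments (paying both compartments' costs).  For
   interior nodes j the recurrences are

       s(vⱼ, ext) = s(vⱼ₋₁, ext) + ℓ̄(vⱼ, ext)
       s(vⱼ, cyt) = min[ s(vⱼ₋₁, ext) + ℓ̄(vⱼ, ext),
                         s(vⱼ₋₁, ext) + ℓ̄(vⱼ₋₁, cyt),
                         s(vⱼ₋₁, cyt) ] + ℓ̄(vⱼ, cyt)
       s(vⱼ, nuc) = min[ s(vⱼ₋₁, cyt) + ℓ̄(vⱼ, cyt),
                         s(vⱼ₋₁, cyt) + ℓ̄(vⱼ₋₁, nuc),
                         s(vⱼ₋₁, nuc) ] + ℓ̄(vⱼ, nuc)

   with base cases s(v₁, ext) = ℓ̄(v₁, ext), s(v₁, cyt) = s(v₁, nuc) = ∞,
   and path score s(v_m, nuc).  Tied paths (equal rᵢ) are re-ordered within
   their tie group by ascending signaling cost; compartment-incoherent
   paths (infinite cost) sink to the bottom of their group.

The compartment chain is configurable (e.g. adding mitochondria), as long
as transitions stay memoryless.  The package also provides the
evidence-based Bayesian edge weighting used to build such interactomes
(per-evidence-type probabilities combined by noisy-OR, capped at 0.75), a
color-coding comparator (`yen_cc`: k best compartment-ordered colorful
paths via Yen's spur search), evaluation statistics (precision/recall, F1,
the path-local *PosFrac* measure, one-sided Mann-Whitney U tests), and a
seeded synthetic benchmark generator with planted, compartment-layered
pathways and decoy routes.

## Worked example

```python
import math
import locpath as lp

spec = lp.SyntheticSpec(seed=7)            # planted pathway + decoys + ties
data = lp.generate(spec)
print("top-3 weight coverage:", round(lp.weight_distribution(data.interactome, 3), 3))

filtered = lp.filter_interactome(data.interactome, data.localization)
print("edges retained by localization filter:", filtered.n_edges())

res = lp.planted_recovery_experiment(spec, k=100, window=10)
loc = res.reranked                          # filter + k shortest paths + re-rank
print("tie groups:", len(loc.tie_groups),
      "| largest:", max(e - s for s, e in loc.tie_groups))
for i in range(6):
    p, s = loc.paths[i], loc.signaling_costs[i]
    print(f"rank {i+1}: {'->'.join(p.nodes)}  r={p.reconstruction_score:.3f} "
          f"s={'inf' if math.isinf(s) else f'{s:.3f}'}")
print("PosFrac mean  baseline:", round(res.mean_plain, 3),
      " localization-aware:", round(res.mean_reranked, 3),
      " one-sided MWU p:", f"{res.mwu_p:.4f}")
```

prints

```
top-3 weight coverage: 0.78
edges retained by localization filter: 350
tie groups: 3 | largest: 97
rank 1: R01->T00  r=0.600  s=inf
rank 2: R04->T00  r=0.600  s=inf
rank 3: R05->T03  r=0.600  s=inf
rank 4: R00->M000->T00  r=0.360  s=1.386
rank 5: R00->M000->T01  r=0.360  s=1.386
rank 6: R00->M000->T03  r=0.360  s=1.386
PosFrac mean  baseline: 0.465  localization-aware: 0.705  one-sided MWU p: 0.0433
```

Reading the output: 78% of edges share just three weight values, so 97 of
the 100 reconstructed paths fall into a single tie group.  The three
top-ranked paths are single interactions — their signaling score is
infinite (a one-hop path cannot start at the membrane *and* end in the
nucleus), but they stay put because their whole tie group is infinite.
Inside the large tie group the re-ranking pulls compartment-coherent
planted paths (finite s = 1.386 = −ln 0.25) above the decoys.  Relative to
the plain reconstruction on the unfiltered interactome, the
localization-aware pipeline (filter, then re-rank) lifts the fraction of
true pathway edges per path (*PosFrac*, averaged over windows of 10 paths)
from 0.465 to 0.705.

The same pipeline is scriptable from the shell:

```sh
locpath synth --seed 7 --outdir fx/
locpath filter --edges fx/edges.tsv --out fx/filtered.tsv
locpath ksp --edges fx/filtered.tsv --receptors fx/receptors.txt --trs fx/trs.txt -k 100 --out fx/paths.tsv
locpath rerank --paths fx/paths.tsv --comppi fx/localization.tsv --out fx/reranked.tsv
locpath eval --paths fx/reranked.tsv --pathway fx/pathway.tsv --edges fx/edges.tsv --window 10 --out fx/eval.json
```

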