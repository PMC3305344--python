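"""Structural cluster map: Tanimoto similarity + Sammon NLM embedding.

Embeds a small mixed compound set in 2D so that fingerprint distances
(1 - TC) are preserved, and pools compounds with TC > 0.85 into clusters.
"""

from metachem import fingerprint, nlm_embed, standardize, tanimoto
from metachem.synth import SynthConfig, generate_metabolite_sets

cfg = SynthConfig(n_setA=40, n_setB=30, n_shared_scaffolds=6,
                  n_unique_scaffolds_A=8, n_unique_scaffolds_B=6, seed=7)
sets = generate_metabolite_sets(cfg)
mets = [standardize(m) for m in sets.metabolites_a + sets.metabolites_b]

fps = [fingerprint(m) for m in mets]
print(f"TC of first two compounds: {tanimoto(fps[0], fps[1]):.3f}")

points, result = nlm_embed(fps, seed=0, ids=[m.id for m in mets], t=0.85)
print(f"embedded {len(points)} compounds; final Sammon stress {result.stress:.4f} "
      f"after {len(result.stress_history)} accepted iterations")
n_clusters = len({p.cluster_id for p in points})
biggest = max(p.cluster_size for p in points)
print(f"{n_clusters} clusters at TC > 0.85; largest cluster has {biggest} compounds")

# Low stress means the 2D layout is faithful to the fingerprint distances;
# cluster sizes are what the dot sizes encode on a structural cluster map.
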