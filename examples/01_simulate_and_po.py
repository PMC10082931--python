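"""Generate a synthetic paired time course and compute polysome occupancy.

Builds the default study design (9 stages x 2 fractions x 3 replicates with
planted translational shifts), applies the log2-intensity noise filter and
derives PO = log2(P) - log2(T) per gene, stage and replicate.
"""
import ponet

cfg = ponet.SimConfig(seed=1)
total, polysomal, truth = ponet.simulate_dataset(cfg)
print(f"simulated {len(total.genes)} genes over stages {cfg.stages}")

total_f, polys_f, removed = ponet.apply_noise_filter(total, polysomal)
print(f"noise filter (log2 intensity < 4 everywhere): removed {len(removed)} genes")

po = ponet.compute_po(total_f, polys_f)
means = po.stage_means()
print("\nmean PO of the first planted up-shifted gene across stages:")
gene = next(g for g, (_, eff) in truth.de_genes.items() if eff > 0)
print(gene, [round(v, 2) for v in means.loc[gene]])
print("a positive step after 12DAF marks increased ribosome association "
      "at the maturation translational shift")
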