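"""Transcript sequence features and planted-motif enrichment.

Generates synthetic transcripts in which one co-regulated module carries a
5'UTR motif, then recovers it: per-region composition, codon-usage bias
(Nc), an exact-p-value PWM scan, and a one-tailed Fisher enrichment test.
"""
import numpy as np

import ponet

_, _, truth = ponet.simulate_dataset(ponet.SimConfig(
    n_genes=200, n_de_up=20, n_de_down=10, n_regulators=4,
    targets_per_regulator=2, n_modules=2, module_size=20, seed=2))

cols = []
for base in "TGACGTCA":
    col = np.full(4, 0.01)
    col["ACGT".index(base)] = 0.97
    cols.append(col)
pwm = ponet.PWM("example_motif", np.array(cols).T)

genes = [f"G{i:04d}" for i in range(1, 201)]
records = ponet.simulate_transcript_set(truth, pwm, genes,
                                        ponet.TranscriptConfig(seed=3))

comp, _ = ponet.sequence_composition(records, "CDS")
nc, excluded = ponet.effective_number_of_codons(records)
print(f"CDS: mean length {comp['length'].mean():.0f} nt, "
      f"mean GC {comp['gc'].mean():.3f}, mean Nc {nc.mean():.1f} "
      f"({len(excluded)} excluded by start/stop/length filters)")
print("the plug-in Nc of a ~150-codon gene sits well below the 61 asymptote "
      "even for unbiased usage: rare codons are simply not sampled")

hits = ponet.pwm_scan(records, pwm, "UTR5", p_threshold=0.001)
module = [g for g, m in truth.modules.items() if m == 1]
res = ponet.motif_enrichment(hits, module, genes)
print(f"\nmotif scan: {len(hits)} hits at p < 0.001; "
      f"module enrichment p = {res['p']:.2e} (odds ratio {res['odds_ratio']:.1f})")
print("the planted module is strongly enriched; a scrambled PWM would not be")
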