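"""Build a core transcriptional regulatory circuitry from planted motifs.

Six TFs get near-deterministic PWMs; each TF's super-enhancer constituent
sequence carries its own motif (auto-regulation) and the motifs of the
other core TFs, so the recovered circuitry is one fully connected clique.
A seventh TF without auto-regulation stays outside.
"""

from cisreg.crc import build_crc, compare_crcs
from cisreg.simulate import SyntheticConfig, generate_pwm_set, plant_motif

cfg = SyntheticConfig(seed=0)
core = [f"TF{i}" for i in range(6)]
outsider = "TF_OUT"
pwms, kmers = generate_pwm_set(cfg, core + [outsider])

seqs = {}
for tf in core:
    seq = "A" * 200
    for i, other in enumerate(core):  # plant every core motif
        seq = plant_motif(seq, kmers[other], [20 * i])
    seqs[tf] = [seq]
seqs[outsider] = ["A" * 200]  # no motifs at all -> not auto-regulated

graph = build_crc(core + [outsider], seqs, pwms, threshold=12.0)
print(f"auto-regulated nodes: {graph.nodes}")
print(f"maximal circuitries: {graph.cliques}")

comparison = compare_crcs({
    "pig": graph.clique_members(),
    "human": set(core[:4]) | {"HS_ONLY"},
    "cattle": set(core[:4]) | {"BT_ONLY"},
})
print(f"\nTFs shared by all three species: {comparison['shared_all']}")
print(f"fraction of the pig circuitry shared by all: "
      f"{comparison['fraction_shared_all']['pig']:.2f}")
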