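"""Windowed repeat density (bp/Mb) along chromosomes.

Plants microsatellites with terminal enrichment (telomere-like pattern) and
a uniformly dispersed transposon family, then compares terminal vs interior
window densities per category.
"""

import numpy as np

from repeatomekit import (
    FamilySpec,
    SimulationConfig,
    simulate_genome,
    window_density,
)

config = SimulationConfig(
    seed=3,
    chromosomes=[("chr1", 500_000), ("chr2", 400_000)],
    families=[
        FamilySpec(name="(CA)n", repeat_class="Simple_repeat",
                   consensus="CA" * 60, copy_number=200,
                   divergence_mean=5.0, placement="end_enriched"),
        FamilySpec(name="Tc1-1", repeat_class="DNA/TcMar-Tc1",
                   consensus_length=600, copy_number=100,
                   divergence_mean=12.0, divergence_sd=6.0),
    ],
)
result = simulate_genome(config)

for category in ("Simple_repeat", "DNA/TcMar-Tc1"):
    tracks = window_density(result.hits, result.genome,
                            category=category, window_size=50_000)
    terminal = [v for t in tracks for v in (t.values[0], t.values[-1])]
    interior = [v for t in tracks for v in t.values[1:-1]]
    print(f"{category}: terminal windows mean {np.mean(terminal):,.0f} bp/Mb, "
          f"interior mean {np.mean(interior):,.0f} bp/Mb "
          f"(ratio {np.mean(terminal) / np.mean(interior):.2f})")

print("\nA terminal/interior ratio well above 1 reproduces the telomeric")
print("clustering of short tandem repeats; dispersed transposons sit near 1.")
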