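"""Summarize a repeat annotation into the classic category table.

Builds a small synthetic genome with planted repeats, round-trips the
annotation through the RepeatMasker .out format, and prints per-category
totals: bp, copies, percent of the repeatome and percent of the genome.
"""

import io

from repeatomekit import (
    FamilySpec,
    SimulationConfig,
    parse_repeatmasker_out,
    simulate_genome,
    summarize_by_category,
    summary_table,
    write_repeatmasker_out,
)

config = SimulationConfig(
    seed=1,
    chromosomes=[("chr1", 200_000)],
    families=[
        FamilySpec(name="Tc1-1", repeat_class="DNA/TcMar-Tc1",
                   consensus_length=500, copy_number=40,
                   divergence_mean=12.0, divergence_sd=5.0),
        FamilySpec(name="(CA)n", repeat_class="Simple_repeat",
                   consensus="CA" * 60, copy_number=50, divergence_mean=5.0),
        FamilySpec(name="unk1", repeat_class="Unknown",
                   consensus_length=400, copy_number=20, divergence_mean=15.0),
    ],
)
result = simulate_genome(config)
hits = parse_repeatmasker_out(io.StringIO(write_repeatmasker_out(result.hits)))
print(summary_table(summarize_by_category(hits, result.genome)))
print("Each row: repeat category, its bp and copy count, its share of all")
print("annotated repeat bp (pct_repeatome) and of the genome (pct_genome).")
print("'Unclassified' collects hits whose class is Unknown.")
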