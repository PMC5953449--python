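"""Synthetic genome generator: mutation model, placement, truth consistency."""

import filecmp
import math

import numpy as np
import pytest

from repeatomekit import (
    FamilySpec,
    SimulationConfig,
    default_config,
    dump_config,
    load_config,
    make_microsat_array,
    mutate_to_divergence,
    parse_repeatmasker_out,
    simulate_genome,
    summarize_by_category,
    truth_table,
    write_simulation,
)
from repeatomekit.cluster import reverse_complement


def binom_se_pct(p: float, n: int) -> float:
    return 100.0 * math.sqrt(p * (1 - p) / n)


@pytest.fixture(scope="module")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        seed=5,
        chromosomes=[("chrA", 100_000), ("chrB", 60_000)],
        families=[
            FamilySpec(name="tx1", repeat_class="DNA/TcMar-Tc1",
                       consensus_length=400, copy_number=40,
                       divergence_mean=12.0, divergence_sd=5.0),
            FamilySpec(name="(CA)n", repeat_class="Simple_repeat",
                       consensus=make_microsat_array("CA", 60),
                       copy_number=50, divergence_mean=5.0,
                       placement="end_enriched"),
            FamilySpec(name="sat1", repeat_class="Satellite/Xba",
                       consensus_length=285, copy_number=30,
                       divergence_mean=3.5, placement="center_enriched"),
        ],
    )


@pytest.fixture(scope="module")
def tiny_result(tiny_config):
    return simulate_genome(tiny_config)


class TestMutate:
    def test_zero_target_returns_consensus(self):
        copy, realized = mutate_to_divergence("ACGTACGTAC", 0.0, seed=1)
        assert copy == "ACGTACGTAC"
        assert realized == 0.0

    def test_realized_within_binomial_bound(self):
        consensus = "ACGT" * 2500  # 10^4 sites
        _, realized = mutate_to_divergence(consensus, 12.0, seed=2)
        assert abs(realized - 12.0) <= 3 * binom_se_pct(0.12, 10_000)

    def test_mean_realized_over_many_seeds(self):
        consensus = "ACGT" * 75  # 300 sites
        target = 3.53
        realized = [
            mutate_to_divergence(consensus, target, seed=s)[1] for s in range(200)
        ]
        se = binom_se_pct(target / 100, 300 * 200)
        assert abs(np.mean(realized) - target) <= 3 * se

    def test_every_changed_site_differs(self):
        copy, realized = mutate_to_divergence("ACGT" * 100, 30.0, seed=3)
        diffs = sum(a != b for a, b in zip(copy, "ACGT" * 100))
        assert realized == pytest.approx(100.0 * diffs / 400)

    def test_deterministic_given_seed(self):
        assert mutate_to_divergence("ACGT" * 50, 10.0, seed=9) == mutate_to_divergence(
            "ACGT" * 50, 10.0, seed=9
        )

    @pytest.mark.parametrize("bad", [-1.0, 75.0])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            mutate_to_divergence("ACGT", bad)


class TestMicrosatArray:
    def test_pure_array(self):
        assert make_microsat_array("CA", 3) == "CACACA"

    def test_length(self):
        assert len(make_microsat_array("AGAT", 25)) == 100

    def test_impurity_rate_within_binomial_bound(self):
        seq = make_microsat_array("CA", 5000, seed=4, impurity_rate=0.05)
        mismatches = sum(a != b for a, b in zip(seq, "CA" * 5000))
        assert abs(mismatches / 10_000 - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / 10_000)


class TestSimulate:
    def test_no_families_gives_pure_background(self):
        config = SimulationConfig(seed=1, chromosomes=[("c", 10_000)])
        result = simulate_genome(config)
        assert result.hits == [] and result.truth == []
        assert result.genome.total_size == 10_000

    def test_deterministic_outputs(self, tiny_config, tmp_path):
        a = write_simulation(simulate_genome(tiny_config), tmp_path / "a")
        b = write_simulation(simulate_genome(tiny_config), tmp_path / "b")
        for key in a:
            assert filecmp.cmp(a[key], b[key], shallow=False), key

    def test_copies_fit_and_do_not_overlap(self, tiny_result):
        by_chrom: dict[str, list] = {}
        for rec in tiny_result.truth:
            assert 0 <= rec.start < rec.end <= tiny_result.genome.length(rec.chromosome)
            by_chrom.setdefault(rec.chromosome, []).append((rec.start, rec.end))
        for intervals in by_chrom.values():
            intervals.sort()
            assert all(a[1] <= b[0] for a, b in zip(intervals, intervals[1:]))

    def test_truth_divergence_exact_against_extracted_sequence(self, tiny_result):
        for rec in tiny_result.truth:
            consensus = tiny_result.consensi[rec.family]
            extracted = tiny_result.genome.sequence(rec.chromosome)[rec.start : rec.end]
            if rec.strand == "-":
                extracted = reverse_complement(extracted)
            diffs = sum(a != b for a, b in zip(extracted, consensus))
            assert rec.divergence == pytest.approx(100.0 * diffs / len(consensus))

    def test_out_round_trip_matches_truth_totals(self, tiny_result, tmp_path):
        paths = write_simulation(tiny_result, tmp_path / "sim")
        hits = parse_repeatmasker_out(paths["out"])
        summaries = summarize_by_category(hits, tiny_result.genome)
        truth_bp: dict[str, int] = {}
        truth_copies: dict[str, int] = {}
        for rec in tiny_result.truth:
            truth_bp[rec.repeat_class] = truth_bp.get(rec.repeat_class, 0) + rec.end - rec.start
            truth_copies[rec.repeat_class] = truth_copies.get(rec.repeat_class, 0) + 1
        for s in summaries:
            assert s.total_bp == truth_bp[s.category]
            assert s.copies == truth_copies[s.category]

    def test_out_divergence_is_truth_rounded(self, tiny_result):
        for hit, rec in zip(tiny_result.hits, tiny_result.truth):
            assert hit.divergence == pytest.approx(round(rec.divergence, 1))

    def test_end_enriched_family_concentrates_at_ends(self, tiny_result):
        terminal = 0
        total = 0
        for rec in tiny_result.truth:
            if rec.family != "(CA)n":
                continue
            length = tiny_result.genome.length(rec.chromosome)
            total += 1
            if rec.start < 0.05 * length or rec.start > 0.95 * length:
                terminal += 1
        # terminal 10% of start positions carries weight 10 => expect ~53% there
        assert total > 0
        assert terminal / total > 0.25

    def test_density_guard(self):
        config = SimulationConfig(
            seed=1,
            chromosomes=[("c", 1000)],
            families=[FamilySpec(name="f", repeat_class="X", consensus_length=100,
                                 copy_number=9, divergence_mean=1.0)],
        )
        with pytest.raises(ValueError, match="80%"):
            simulate_genome(config)

    def test_truth_table_has_one_row_per_copy(self, tiny_result):
        text = truth_table(tiny_result.truth)
        assert len(text.splitlines()) == len(tiny_result.truth) + 1


class TestConfigIO:
    def test_yaml_round_trip(self, tiny_config, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(dump_config(tiny_config))
        loaded = load_config(path)
        assert loaded == tiny_config

    def test_default_config_is_study_scale(self):
        config = default_config()
        assert sum(length for _, length in config.chromosomes) == 5_000_000
        names = {f.name for f in config.families}
        assert {"Tc1-1_Ip", "Xba", "(CA)n"} <= names
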