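"""Conversion-as-variant DMP calling: consensus, chemistry decoding,
context annotation and DMG aggregation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftomics import methylome as my
from graftomics import simulate as sim
from graftomics.config import SimConfig
from graftomics.errors import InputError, SiteTypeError

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestConsensus:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"C": 12}, "C"),
            ({"C": 5, "T": 5}, "ambiguous"),
            ({"C": 4}, "ambiguous"),           # depth gate at 5
            ([{"C": 3}, {"C": 3}], "C"),       # replicates pooled
            ({"C": 9, "T": 1}, "C"),
            ({"C": 8, "T": 2}, "ambiguous"),   # 0.8 < 0.9 fraction gate
        ],
    )
    def test_consensus(self, counts, expected):
        assert my.consensus_allele(counts) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            my.consensus_allele({"C": -1})


class TestChemistryDecoding:
    @pytest.mark.parametrize(
        "ref, strand, allele, expected",
        [
            ("C", "+", "T", "unmethylated"),
            ("C", "+", "C", "methylated"),
            ("G", "-", "G", "methylated"),
            ("G", "-", "A", "unmethylated"),
            ("C", "+", "A", "uninformative"),
            ("G", "-", "ambiguous", "uninformative"),
        ],
    )
    def test_methylation_state(self, ref, strand, allele, expected):
        assert my.methylation_state(ref, strand, allele) == expected

    def test_non_cytosine_site_is_an_error(self):
        with pytest.raises(SiteTypeError):
            my.methylation_state("A", "+", "A")
        with pytest.raises(SiteTypeError):
            my.methylation_state("C", "-", "C")

    @pytest.mark.parametrize(
        "control, grafted, expected",
        [
            ("methylated", "unmethylated", "hypo"),
            ("unmethylated", "methylated", "hyper"),
            ("methylated", "methylated", "none"),
            ("uninformative", "methylated", "none"),
        ],
    )
    def test_call_dmp(self, control, grafted, expected):
        assert my.call_dmp(control, grafted) == expected


class TestContext:
    def test_plus_strand_examples(self):
        assert my.classify_context("ACGTT", 1, "+") == "CG"
        assert my.classify_context("ACAGT", 1, "+") == "CHG"
        assert my.classify_context("ACAAT", 1, "+") == "CHH"

    def test_truncated_neighbourhood_is_na(self):
        assert my.classify_context("AC", 1, "+") == "NA"
        assert my.classify_context("GA", 0, "-") == "NA"

    def test_minus_strand_against_reverse_complement_oracle(self):
        # every dinucleotide neighbourhood upstream of a plus-frame G
        for b1 in "ACGT":
            for b2 in "ACGT":
                seq = b2 + b1 + "G" + "AA"
                read = COMP[b1] + COMP[b2]  # 5'->3' on the cytosine strand
                expected = "CG" if read[0] == "G" else ("CHG" if read[1] == "G" else "CHH")
                assert my.classify_context(seq, 2, "-") == expected, seq

    @given(st.text(alphabet="ACGT", min_size=5, max_size=60))
    @settings(max_examples=60, derandomize=True)
    def test_context_partition(self, seq):
        # every cytosine site with a full neighbourhood has exactly one context
        for i, b in enumerate(seq):
            if b == "C" and i + 2 < len(seq):
                assert my.classify_context(seq, i, "+") in {"CG", "CHG", "CHH"}
            if b == "G" and i - 2 >= 0:
                assert my.classify_context(seq, i, "-") in {"CG", "CHG", "CHH"}


def _simulated_calls(seed=7, error=0.0, dmp_rate=0.01):
    cfg = SimConfig(n_genes=30, gene_length_bp=300, intergenic_bp=100,
                    dmp_rate=dmp_rate, error_rate=error, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    seqs, genes = sim.generate_reference(cfg, rng)
    sites = sim.cytosine_sites(seqs)
    truth = sim.plant_methylation_truth(cfg, sites, rng)
    table = sim.simulate_methyl_calls(cfg, truth, seqs, rng)
    return seqs, genes, truth, table


class TestCallDmps:
    def test_error_free_round_trip_recovers_planted_flips_exactly(self):
        seqs, _, truth, table = _simulated_calls()
        dmps = my.call_dmps(table, seqs)
        called = set(zip(dmps["pos"], dmps["strand"], dmps["direction"]))
        planted = truth[truth["dmp_direction"] != "none"]
        expected = set(zip(planted["pos"] + 1, planted["strand"], planted["dmp_direction"]))
        assert called == expected

    def test_condition_swap_flips_every_direction(self):
        seqs, _, _, table = _simulated_calls()
        dmps = my.call_dmps(table, seqs)
        swapped = table.copy()
        swapped["cond"] = swapped["cond"].map({"control": "grafted", "grafted": "control"})
        dmps_sw = my.call_dmps(swapped, seqs)
        merged = dmps.merge(dmps_sw, on=["chrom", "pos", "strand", "context"],
                            suffixes=("_a", "_b"))
        assert len(merged) == len(dmps) == len(dmps_sw)
        assert (merged["direction_a"] != merged["direction_b"]).all()

    def test_contexts_annotated(self):
        seqs, _, _, table = _simulated_calls()
        dmps = my.call_dmps(table, seqs)
        seq = seqs["chr1"]
        comp = COMP
        for row in dmps.itertuples(index=False):
            pos0 = row.pos - 1
            if row.strand == "+":
                down = seq[pos0 + 1 : pos0 + 3]
            else:
                down = "".join(comp[b] for b in reversed(seq[max(pos0 - 2, 0) : pos0]))
            if len(down) >= 1 and down[0] == "G":
                expected = "CG"
            elif len(down) == 2:
                expected = "CHG" if down[1] == "G" else "CHH"
            else:
                expected = "NA"
            assert row.context == expected


class TestAggregateDmgs:
    GENES = pd.DataFrame(
        {"gene_id": ["gA", "gB"], "chrom": "chr1",
         "start": [100, 400], "end": [300, 600], "strand": ["+", "-"]}
    )

    def _dmps(self, specs):
        # specs: list of (pos, direction)
        return pd.DataFrame(
            {"chrom": "chr1", "pos": [p for p, _ in specs], "strand": "+",
             "context": "CG", "direction": [d for _, d in specs]}
        )

    def test_hyper_only_summary(self):
        dmps = self._dmps([(150 + i, "hyper") for i in range(11)])
        out = my.aggregate_dmgs(dmps, self.GENES, threshold_k=1)
        assert len(out) == 1
        assert out.iloc[0]["gene_id"] == "gA"
        assert out.iloc[0]["summary"] == "+11"

    def test_mixed_direction_summary(self):
        dmps = self._dmps([(150, "hyper"), (160, "hypo"), (170, "hypo")])
        out = my.aggregate_dmgs(dmps, self.GENES, threshold_k=1)
        assert out.iloc[0]["summary"] == "1 / -2"
        assert out.iloc[0]["n_hyper"] == 1 and out.iloc[0]["n_hypo"] == 2

    def test_threshold_k_filters_genes(self):
        dmps = self._dmps([(150, "hyper"), (160, "hyper"), (170, "hyper")])
        assert len(my.aggregate_dmgs(dmps, self.GENES, threshold_k=5)) == 0
        assert len(my.aggregate_dmgs(dmps, self.GENES, threshold_k=3)) == 1

    def test_gene_without_dmps_is_absent(self):
        dmps = self._dmps([(150, "hyper")])
        out = my.aggregate_dmgs(dmps, self.GENES)
        assert "gB" not in set(out["gene_id"])

    def test_net_mode(self):
        dmps = self._dmps([(150, "hyper"), (160, "hypo")])
        assert len(my.aggregate_dmgs(dmps, self.GENES, threshold_k=1, mode="net")) == 0

    def test_flank_extends_the_interval(self):
        dmps = self._dmps([(95, "hyper")])  # 5 bp upstream of gA
        assert len(my.aggregate_dmgs(dmps, self.GENES, flank_bp=0)) == 0
        out = my.aggregate_dmgs(dmps, self.GENES, flank_bp=10)
        assert list(out["gene_id"]) == ["gA"]
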