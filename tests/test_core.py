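"""Core-microbiome delineation: evenness statistic, filters, consensus taxonomy."""

import numpy as np
import pandas as pd
import pytest

from amplicore import (CoreCriteria, CoreMicrobiome, OtuTable, TaxonomyTable,
                       consensus_taxonomy, delineate_core, otu_evenness)
from conftest import CORE_EVENNESS_ROWS


def make_table(columns: dict, sample_ids=None, filler_total=2000, seed=0):
    """Table holding the given OTU columns plus abundant filler so sample
    totals are realistic (~filler_total reads)."""
    n = len(next(iter(columns.values())))
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(columns, index=sample_ids)
    filler = rng.integers(filler_total // 8, filler_total // 4, size=(n, 4))
    for j in range(4):
        frame[f"Filler{j}"] = filler[:, j]
    return OtuTable(frame)


class TestOtuEvenness:
    @pytest.mark.parametrize("counts, expected", CORE_EVENNESS_ROWS)
    def test_published_rows(self, counts, expected):
        assert otu_evenness(counts) == pytest.approx(expected, abs=5e-4)

    def test_concentrated_otu_scores_low(self):
        assert otu_evenness((100, 3, 3, 3, 3)) == pytest.approx(0.304, abs=1e-3)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            otu_evenness([0, 0, 0])


class TestDelineation:
    def test_even_abundant_otu_is_core(self):
        t = make_table({"OtuA": [4, 3, 4, 6, 6]}, filler_total=2000)
        rep = delineate_core(t)
        assert "OtuA" in rep.core_otus
        row = rep.data.loc["OtuA"]
        assert row["evenness"] == pytest.approx(0.979, abs=5e-4)

    def test_min_reads_rule(self):
        t = make_table({"OtuA": [2, 5, 5, 5, 5]})
        rep = delineate_core(t)
        assert "OtuA" not in rep.core_otus
        assert not rep.data.loc["OtuA", "pass_min_reads"]
        assert rep.data.loc["OtuA", "pass_evenness"]

    def test_evenness_rule(self):
        t = make_table({"OtuA": [100, 3, 3, 3, 3]})
        rep = delineate_core(t)
        assert "OtuA" not in rep.core_otus
        assert not rep.data.loc["OtuA", "pass_evenness"]

    def test_frequency_rule_binds_at_depth(self):
        # 3 reads everywhere passes the read floor but at 4000-read samples
        # 3/4000 < 0.1%, so the frequency filter alone rejects it
        t = make_table({"OtuA": [3, 3, 3, 3, 3]}, filler_total=8000)
        rep = delineate_core(t)
        assert rep.data.loc["OtuA", "pass_min_reads"]
        assert not rep.data.loc["OtuA", "pass_min_freq"]
        assert "OtuA" in rep.near_misses().index

    def test_core_flag_is_conjunction(self, random_table_factory):
        t = random_table_factory(seed=20, n_otus=60, max_count=30)
        rep = delineate_core(t)
        expected = (rep.data["pass_min_reads"] & rep.data["pass_min_freq"]
                    & rep.data["pass_evenness"])
        assert (rep.data["core"] == expected).all()

    def test_order_invariance(self, random_table_factory):
        t = random_table_factory(seed=21, n_otus=50, max_count=40)
        shuffled = OtuTable(t.counts.iloc[::-1, ::-1], label=t.label,
                            drop_empty=False)
        assert set(delineate_core(t).core_otus) == \
            set(delineate_core(shuffled).core_otus)

    def test_threshold_monotonicity(self, random_table_factory):
        """Raising any threshold never adds a core OTU."""
        t = random_table_factory(seed=22, n_otus=80, max_count=60)
        base = set(delineate_core(t, CoreCriteria(0.5, 1, 0.0)).core_otus)
        for crit in [CoreCriteria(0.7, 1, 0.0), CoreCriteria(0.9, 1, 0.0),
                     CoreCriteria(0.5, 3, 0.0), CoreCriteria(0.5, 5, 0.0),
                     CoreCriteria(0.5, 1, 0.001), CoreCriteria(0.5, 1, 0.01)]:
            stricter = set(delineate_core(t, crit).core_otus)
            assert stricter <= base
            base_for_next = stricter  # noqa: F841 (grid is vs the loosest)

    def test_duplicated_samples_perfect_evenness(self):
        row = np.array([5, 1, 9, 0, 40, 3])
        frame = pd.DataFrame([row] * 4, index=list("ABCD"),
                             columns=[f"o{i}" for i in range(6)])
        rep = delineate_core(OtuTable(frame), CoreCriteria(0.9, 3, 0.0))
        for otu in rep.data.index:
            counts = rep.data.loc[otu, list("ABCD")].to_numpy(dtype=float)
            if (counts >= 3).all():
                assert otu in rep.core_otus
                assert rep.data.loc[otu, "evenness"] == pytest.approx(1.0)

    def test_averaged_table_flagged(self):
        t = make_table({"OtuA": [4.2, 3.4, 4.0, 6.2, 6.0]})
        rep = delineate_core(t)
        assert rep.averaged
        assert "averaged" in rep.summary()

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            CoreCriteria(evenness_min=1.5)
        with pytest.raises(ValueError):
            CoreCriteria(min_reads_per_sample=0)
        with pytest.raises(ValueError):
            CoreCriteria(min_freq_per_sample=1.0)

    def test_taxonomy_annotation_and_summary(self):
        t = make_table({"OtuA": [4, 3, 4, 6, 6]})
        tax = TaxonomyTable({"OtuA": ["Bacteria", "Proteobacteria"]})
        rep = CoreMicrobiome(t, tax).fit()
        assert rep.data.loc["OtuA", "taxonomy"] == "Bacteria;Proteobacteria;"
        assert "OtuA" in rep.summary()


class TestConsensusTaxonomy:
    def test_unanimous_returns_verbatim(self):
        lin = ["Bacteria", "Proteobacteria", "Alphaproteobacteria"]
        assert consensus_taxonomy([lin, lin, lin]) == \
            "Bacteria;Proteobacteria;Alphaproteobacteria;"

    def test_single_member(self):
        assert consensus_taxonomy([["Bacteria", "Chloroflexi"]]) == \
            "Bacteria;Chloroflexi;"

    def test_majority_breaks_at_genus(self):
        members = [["Bacteria", "Proteobacteria", "FamX", "GenA"],
                   ["Bacteria", "Proteobacteria", "FamX", "GenA"],
                   ["Bacteria", "Proteobacteria", "FamX", "GenB"]]
        # 2 of 3 at genus is a majority; flip one to break it
        assert consensus_taxonomy(members).endswith("GenA;")
        members[1][3] = "GenC"
        assert consensus_taxonomy(members) == \
            "Bacteria;Proteobacteria;FamX;unclassified;"

    def test_below_first_failure_all_unclassified(self):
        members = [["Bacteria", "P1", "C1"], ["Bacteria", "P2", "C1"]]
        assert consensus_taxonomy(members) == \
            "Bacteria;unclassified;unclassified;"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_taxonomy([])
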