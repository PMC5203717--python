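"""OTU table I/O, QC filters, rarefaction, aggregation and summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from pneumotyper.simulate import default_config, generate_cohort
from pneumotyper.table import (
    OtuTable,
    aggregate_rank,
    categorize_dna_concentration,
    cohort_summary,
    exclude_diversity_outliers,
    filter_min_depth,
    format_count_percent,
    rarefy,
    read_otu_table,
)


class TestReadOtuTable:
    def test_round_trip(self, toy_table, tmp_path):
        toy_table.write(tmp_path / "c.tsv", tmp_path / "t.tsv")
        back = read_otu_table(tmp_path / "c.tsv", tmp_path / "t.tsv")
        pd.testing.assert_frame_equal(
            back.counts, toy_table.counts, check_names=False
        )
        assert back.genus("OTU1") == "Streptococcus"
        assert back.genus("OTU3") == "Moraxella"

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("sample_id\tOTU1\n")
        with pytest.raises(ValueError, match="no samples"):
            read_otu_table(path)

    def test_partial_lineage_leaves_ranks_empty(self, tmp_path):
        (tmp_path / "c.tsv").write_text("sample_id\tOTU4\ns1\t3\n")
        (tmp_path / "t.tsv").write_text("otu_id\tlineage\nOTU4\tBacteria;Firmicutes\n")
        tab = read_otu_table(tmp_path / "c.tsv", tmp_path / "t.tsv")
        assert tab.taxonomy.loc["OTU4", "phylum"] == "Firmicutes"
        assert tab.taxonomy.loc["OTU4", "genus"] == ""

    @pytest.mark.parametrize(
        "counts, message",
        [
            ([[1, -2]], "negative count"),
            ([[1, 2.5]], "non-integer count"),
        ],
    )
    def test_bad_cells_are_named(self, counts, message):
        df = pd.DataFrame(counts, index=["s1"], columns=["OTU1", "OTU2"], dtype=float)
        with pytest.raises(ValueError, match=message) as err:
            OtuTable(df)
        assert "OTU2" in str(err.value)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([[1], [2]], index=["s1", "s1"], columns=["OTU1"])
        with pytest.raises(ValueError, match="duplicate sample ids"):
            OtuTable(df)

    def test_relative_abundance_sums_to_one(self, toy_table):
        rel = toy_table.relative_abundance()
        assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-9)


class TestDepthFilter:
    def test_boundary_at_threshold(self):
        counts = pd.DataFrame(
            {"OTU1": [1999, 2000, 52749]}, index=["a", "b", "c"]
        )
        kept, report = filter_min_depth(OtuTable(counts), 2000)
        assert kept.sample_ids == ["b", "c"]
        assert report["sample_id"].tolist() == ["a"]
        assert report["depth"].tolist() == [1999]

    def test_identity_when_all_deep(self, toy_table):
        kept, report = filter_min_depth(toy_table, 1)
        assert kept.sample_ids == toy_table.sample_ids
        assert report.empty

    def test_synthetic_cohort_exclusion_rate(self):
        # depth model puts 5 % of samples below 2000 reads by construction
        cohort = generate_cohort(default_config(n_subjects=400, seed=5))
        _, report = filter_min_depth(cohort.table, 2000)
        frac = len(report) / cohort.table.n_samples
        n = cohort.table.n_samples
        ci = 3 * math.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < ci


class TestDiversityOutliers:
    def test_identical_samples_nothing_removed(self):
        counts = pd.DataFrame([[5, 5]] * 4, columns=["a", "b"])
        counts.index = [f"s{i}" for i in range(4)]
        kept, report = exclude_diversity_outliers(OtuTable(counts))
        assert kept.n_samples == 4 and report.empty

    def test_planted_high_diversity_sample_removed(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(100):  # near-monocultures, SDI ~ 0.1
            row = np.zeros(64, dtype=int)
            row[rng.integers(64)] = 1950
            row[rng.integers(64)] = 50
            rows.append(row)
        rows.append(np.full(64, 2000 // 64))  # uniform: SDI = ln 64 ~ 4.16
        counts = pd.DataFrame(rows, index=[f"s{i}" for i in range(101)])
        counts.columns = [f"o{j}" for j in range(64)]
        kept, report = exclude_diversity_outliers(OtuTable(counts), z=5)
        assert report["sample_id"].tolist() == ["s100"]
        assert kept.n_samples == 100

    def test_infinite_z_is_identity(self, toy_table):
        kept, report = exclude_diversity_outliers(toy_table, z=np.inf)
        assert kept.n_samples == toy_table.n_samples and report.empty


class TestRarefy:
    def test_single_otu_forced_outcome(self):
        counts = pd.DataFrame({"OTU1": [5000]}, index=["s1"])
        rare = rarefy(OtuTable(counts), 2000, seed=1)
        assert rare.counts.loc["s1", "OTU1"] == 2000

    def test_conserves_depth_and_is_reproducible(self, toy_table):
        tab = OtuTable(toy_table.counts * 1000)
        r1 = rarefy(tab, 2000, seed=9)
        r2 = rarefy(tab, 2000, seed=9)
        assert (r1.depths() == 2000).all()
        pd.testing.assert_frame_equal(r1.counts, r2.counts)

    def test_shallow_sample_raises_with_name(self, toy_table):
        with pytest.raises(ValueError, match="s1"):
            rarefy(toy_table, 2000, seed=0)

    def test_hypergeometric_expectation(self):
        # (A=9000, B=1000) at depth 2000: E[B] = 200, sd = 12
        counts = pd.DataFrame({"A": [9000], "B": [1000]}, index=["s"])
        tab = OtuTable(counts)
        draws = [
            rarefy(tab, 2000, seed=s).counts.loc["s", "B"] for s in range(300)
        ]
        assert abs(np.mean(draws) - 200) < 3 * 12 / math.sqrt(300)


class TestAggregateRank:
    def test_additivity_and_conservation(self, toy_table):
        agg = aggregate_rank(toy_table, "genus")
        assert agg.counts.loc["s1", "Streptococcus"] == 5
        assert agg.counts.loc["s2", "Streptococcus"] == 7
        assert (agg.depths() == toy_table.depths()).all()

    def test_unclassified_pooling(self, toy_table):
        toy_table.taxonomy.loc["OTU3", "genus"] = ""
        agg = aggregate_rank(toy_table, "genus")
        assert "unclassified" in agg.otu_ids

    def test_cohort_genus_trajectories_match_configuration(self, big_cohort):
        # the default world is calibrated to the stated genus succession:
        # Staphylococcus 49/22/10 %, Streptococcus 17/31/29 %, Moraxella
        # 9/13/23 % of reads at the three visits
        agg = aggregate_rank(big_cohort.table, "genus")
        rel = agg.relative_abundance()
        meta = big_cohort.metadata.set_index("sample_id")
        expected = {
            "Staphylococcus": [0.49, 0.22, 0.10],
            "Streptococcus": [0.17, 0.31, 0.29],
            "Moraxella": [0.09, 0.13, 0.23],
        }
        for genus, targets in expected.items():
            for t, target in zip(["W1", "M1", "M3"], targets):
                observed = rel.loc[meta.index[meta.timepoint == t], genus].mean()
                assert observed == pytest.approx(target, abs=0.02), (genus, t)


class TestDnaConcentration:
    @pytest.mark.parametrize(
        "conc, label",
        [
            (0.05, "extremely_low"),
            (0.1, "very_low"),
            (0.33, "low"),       # boundary: 0.33 is not < 0.33
            (0.79, "low"),
            (1.0, "medium"),
            (2.0, "high"),
            (4.58, "very_high"),  # top bin closed below
            (100.0, "very_high"),
        ],
    )
    def test_bins(self, conc, label):
        assert categorize_dna_concentration(conc) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            categorize_dna_concentration(-0.1)


class TestCohortSummary:
    def test_format_zero_case(self):
        assert format_count_percent(0, 17, 1) == "0 (0.0%)"

    def test_summary_counts_subjects_once(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1"],
                "subject_id": ["A", "A", "B"],
                "timepoint": ["W1", "M1", "W1"],
                "sex": ["male", "male", "female"],
                "siblings": [True, True, False],
                "csection": [False, False, True],
                "mother_asthma": [False, False, False],
                "antibiotics": [False, True, False],
                "exclusively_breastfed": [True, True, True],
            }
        )
        out = cohort_summary(meta)
        boys = out[(out.field == "sex") & (out.group == "all_subjects")].iloc[0]
        assert boys["n"] == 1 and boys["denominator"] == 2
        assert boys["label"] == "1 (50%)"

    def test_explicit_denominator_for_missing_covariates(self):
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(4)],
                "subject_id": [f"S{i}" for i in range(4)],
                "timepoint": ["W1"] * 4,
                "siblings": [True, True, True, None],
            }
        )
        out = cohort_summary(
            meta, denominators={("siblings", "all_subjects"): 3}, decimals=1
        )
        row = out[out.field == "siblings"].iloc[0]
        assert row["label"] == "3 (100.0%)"
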