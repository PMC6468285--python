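"""Occupancy estimation, condition ratios, tAI and enrichment profiles."""

import numpy as np
import pandas as pd
import pytest

from riboq import (
    DwellConfig,
    OccupancyProfile,
    TAIParameters,
    Transcript,
    TranscriptomeFixture,
    bulk_codon_occupancy,
    c_vs_u_ratio,
    compute_tai,
    generate_transcriptome,
    load_tai_parameters,
    local_codon_usage,
    occupancy_ratio,
    occupancy_tai_correlation,
    relative_enrichment_profile,
    simulate_footprints,
)
from riboq.core import SENSE_CODONS
from riboq.synthetic_data import truth_to_asites

from conftest import make_asites


@pytest.fixture()
def context_tx():
    # gene: ATG GAC AAA AAA GAC TAA  -> codons indexed 0..5
    t = Transcript("ctx", "ATG" + "GAC" + "AAA" + "AAA" + "GAC" + "TAA")
    return TranscriptomeFixture([t])


class TestLocalCodonUsage:
    def test_single_read_context_tally(self, context_tx):
        # A-site on codon 1 -> context codons 2,3,4 = AAA,AAA,GAC
        asites = make_asites([("r0", "ctx", 1, "GAC")])
        usage = local_codon_usage(asites, context_tx)
        assert usage["AAA"] == pytest.approx(2 / 3)
        assert usage["GAC"] == pytest.approx(1 / 3)

    def test_two_read_tally(self, context_tx):
        # contexts: ci=1 -> (AAA,AAA,GAC); ci=0 -> (GAC,AAA,AAA)
        asites = make_asites([("r0", "ctx", 1, "GAC"), ("r1", "ctx", 0, "ATG")])
        usage = local_codon_usage(asites, context_tx)
        assert usage["AAA"] == pytest.approx(4 / 6)
        assert usage["GAC"] == pytest.approx(2 / 6)

    def test_last_sense_codon_contributes_no_context(self, context_tx):
        # ci=4 is the last sense codon; its context is empty (stop truncates)
        asites = make_asites([("r0", "ctx", 4, "GAC"), ("r1", "ctx", 1, "GAC")])
        usage = local_codon_usage(asites, context_tx)
        assert usage.sum() == pytest.approx(1.0)
        assert usage["AAA"] == pytest.approx(2 / 3)  # only r1's context counts


class TestBulkOccupancy:
    def test_self_normalization_gives_unity(self):
        asites = make_asites(
            [("r%d" % i, "g", 0, c) for i, c in enumerate(["AAA"] * 2 + ["GAC"] * 2)]
        )
        usage = pd.Series(0.0, index=list(SENSE_CODONS))
        usage[["AAA", "GAC"]] = 0.5
        prof = bulk_codon_occupancy(asites, usage, min_count=1)
        assert prof.occupancy["AAA"] == pytest.approx(1.0)
        assert prof.occupancy["GAC"] == pytest.approx(1.0)

    def test_hand_division(self):
        rows = [("r%d" % i, "g", 0, "AAA") for i in range(3)] + [("x", "g", 0, "GAC")]
        usage = pd.Series(0.0, index=list(SENSE_CODONS))
        usage[["AAA", "GAC"]] = 0.5
        prof = bulk_codon_occupancy(make_asites(rows), usage, min_count=1)
        assert prof.occupancy["AAA"] == pytest.approx(1.5)
        assert prof.occupancy["GAC"] == pytest.approx(0.5)

    def test_zero_usage_missing_not_infinite(self):
        asites = make_asites([("r0", "g", 0, "AAA")])
        usage = pd.Series(0.0, index=list(SENSE_CODONS))
        usage["GAC"] = 1.0
        prof = bulk_codon_occupancy(asites, usage, min_count=1)
        assert np.isnan(prof.occupancy["AAA"])
        assert np.isfinite(prof.occupancy.dropna()).all()

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            bulk_codon_occupancy(make_asites([]), pd.Series(dtype=float))

    def test_proportions_normalized(self, small_tx):
        sim = simulate_footprints(small_tx, depth=5000, seed=3)
        asites = truth_to_asites(small_tx, sim.truth)
        prof = bulk_codon_occupancy(asites, local_codon_usage(asites, small_tx))
        assert prof.table["proportion"].sum() == pytest.approx(1.0, abs=1e-9)
        assert prof.table["usage"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_under_read_duplication(self, small_tx):
        sim = simulate_footprints(small_tx, depth=2000, seed=4)
        asites = truth_to_asites(small_tx, sim.truth)
        doubled = pd.concat([asites, asites], ignore_index=True)
        p1 = bulk_codon_occupancy(asites, local_codon_usage(asites, small_tx), min_count=1)
        p2 = bulk_codon_occupancy(doubled, local_codon_usage(doubled, small_tx), min_count=1)
        pd.testing.assert_series_equal(p1.occupancy, p2.occupancy)

    def test_brute_force_oracle_equivalence(self, small_tx):
        """Vectorized occupancy equals a plain-loop recomputation exactly."""
        sim = simulate_footprints(small_tx, depth=4000, seed=5)
        asites = truth_to_asites(small_tx, sim.truth)
        prof = bulk_codon_occupancy(asites, local_codon_usage(asites, small_tx), min_count=1)
        # independent recomputation with dict arithmetic
        a_counts: dict[str, int] = {}
        u_counts: dict[str, int] = {}
        for row in asites.itertuples():
            a_counts[row.codon] = a_counts.get(row.codon, 0) + 1
            t = small_tx.get(row.gene_id)
            for j in range(row.a_site_codon_index + 1, row.a_site_codon_index + 4):
                if j <= t.n_codons - 2:
                    c = t.codons[j]
                    u_counts[c] = u_counts.get(c, 0) + 1
        na, nu = sum(a_counts.values()), sum(u_counts.values())
        for codon, cnt in a_counts.items():
            if codon in u_counts:
                expected = (cnt / na) / (u_counts[codon] / nu)
                assert prof.occupancy[codon] == pytest.approx(expected, rel=1e-12)


class TestOccupancyRatio:
    @staticmethod
    def _profile(occ: dict, sample="s"):
        table = pd.DataFrame(
            {"occupancy": pd.Series(occ, dtype=float).reindex(list(SENSE_CODONS))}
        )
        return OccupancyProfile(sample, table)

    def test_identity_gives_unit_ratio_zero_sem(self):
        reps = [self._profile({"AAA": 1.2, "GAC": 0.8}) for _ in range(3)]
        out = occupancy_ratio(reps, reps)
        assert (out["mean"] == 1.0).all()
        assert (out["sem"] == 0.0).all()
        assert (out["n_replicates"] == 3).all()

    def test_paired_mean_and_sem_hand_computed(self):
        num = [self._profile({"AAA": v}) for v in (2.0, 2.2, 1.8)]
        den = [self._profile({"AAA": v}) for v in (1.0, 1.0, 1.0)]
        out = occupancy_ratio(num, den)
        assert out.loc["AAA", "mean"] == pytest.approx(2.0)
        assert out.loc["AAA", "sem"] == pytest.approx(np.std([2.0, 2.2, 1.8], ddof=1) / np.sqrt(3))

    def test_zero_denominator_codon_omitted(self):
        num = [self._profile({"AAA": 1.0, "GAC": 1.0})] * 2
        den = [self._profile({"AAA": 1.0, "GAC": 0.0})] * 2
        with pytest.warns(UserWarning):
            out = occupancy_ratio(num, den)
        assert "GAC" not in out.index and "AAA" in out.index

    def test_unequal_replicates_rejected(self):
        p = self._profile({"AAA": 1.0})
        with pytest.raises(ValueError):
            occupancy_ratio([p, p], [p])

    def test_dwell_recovery_single_codon(self, small_tx):
        """Injected GAC dwell 2.0 recovered as a ratio near 2, others near 1."""
        tx = generate_transcriptome(40, (200, 300), seed=71, abundance_sigma=0.0)
        num, den = [], []
        for r in range(3):
            s_num = simulate_footprints(tx, DwellConfig({"GAC": 2.0}), depth=60000, seed=710 + r)
            s_den = simulate_footprints(tx, depth=60000, seed=720 + r)
            for sim, dest in ((s_num, num), (s_den, den)):
                a = truth_to_asites(tx, sim.truth)
                dest.append(bulk_codon_occupancy(a, local_codon_usage(a, tx)))
        out = occupancy_ratio(num, den)
        assert out.loc["GAC", "mean"] == pytest.approx(2.0, rel=0.1)
        others = out["mean"].drop("GAC")
        # off-target ratios center on 1 (tight bands are exercised at full depth)
        assert abs(others.mean() - 1) < 0.02
        assert (others - 1).abs().quantile(0.9) < 0.1


class TestCvsURatio:
    def test_direct_division_and_propagated_sem(self):
        ratios = pd.DataFrame(
            {"mean": [1.2, 1.0], "sem": [0.06, 0.05], "n_replicates": 3},
            index=["GAC", "GAT"],
        )
        out = c_vs_u_ratio(ratios, [("GAC", "GAT")])
        assert out.loc[0, "ratio"] == pytest.approx(1.2)
        expected_sem = 1.2 * np.sqrt((0.06 / 1.2) ** 2 + (0.05 / 1.0) ** 2)
        assert out.loc[0, "sem"] == pytest.approx(expected_sem)

    def test_equal_ratios_give_unity(self):
        ratios = pd.DataFrame(
            {"mean": [0.9, 0.9], "sem": [0.0, 0.0], "n_replicates": 3},
            index=["AAC", "AAT"],
        )
        assert c_vs_u_ratio(ratios, [("AAC", "AAT")]).loc[0, "ratio"] == pytest.approx(1.0)

    def test_non_synonymous_pair_rejected(self):
        ratios = pd.DataFrame(
            {"mean": [1.0, 1.0], "sem": [0.0, 0.0]}, index=["GAC", "AAT"]
        )
        with pytest.raises(ValueError):
            c_vs_u_ratio(ratios, [("GAC", "AAT")])


class TestTAI:
    def test_watson_crick_self_maximum(self):
        params = TAIParameters(
            tgcn={"GTC": 10},  # decodes GAC by Watson-Crick
            s_values={"I:U": 0.0, "G:C": 0.0, "U:A": 0.0, "C:G": 0.0,
                      "G:U": 1.0, "I:C": 1.0, "I:A": 1.0, "U:G": 1.0},
        )
        tai = compute_tai(params)
        assert tai.loc["GAC", "tai"] == pytest.approx(1.0)
        assert tai.loc["GAC", "w"] == pytest.approx(10.0)

    def test_wobble_only_half_weight(self):
        # GAT reachable only via G:U wobble from GTC with s=0.5 -> w=5, max w=10
        params = TAIParameters(
            tgcn={"GTC": 10},
            s_values={"I:U": 1.0, "G:C": 0.0, "U:A": 1.0, "C:G": 1.0,
                      "G:U": 0.5, "I:C": 1.0, "I:A": 1.0, "U:G": 1.0},
        )
        tai = compute_tai(params)
        assert tai.loc["GAT", "tai"] == pytest.approx(0.5)

    def test_zero_weight_codon_imputed_with_geometric_mean(self):
        params = TAIParameters(
            tgcn={"GTC": 10, "GTT": 5},
            s_values={"I:U": 0.0, "G:C": 0.0, "U:A": 0.0, "C:G": 0.0,
                      "G:U": 1.0, "I:C": 1.0, "I:A": 1.0, "U:G": 1.0},
        )
        tai = compute_tai(params)
        assert tai["imputed"].sum() == 59
        from scipy.stats import gmean

        expected = gmean([10.0, 5.0])
        assert tai.loc["AAA", "w"] == pytest.approx(expected)

    def test_negative_copy_number_rejected(self):
        with pytest.raises(ValueError):
            TAIParameters(tgcn={"GTC": -1}, s_values={})

    def test_bundled_tables_cover_all_codons(self):
        tai = compute_tai(load_tai_parameters())
        assert tai["tai"].between(0, 1).all()
        assert tai["tai"].max() == 1.0
        assert not tai["imputed"].any()


class TestTaiCorrelation:
    def _profile_from(self, values: pd.Series):
        return OccupancyProfile("s", pd.DataFrame({"occupancy": values}))

    def test_monotone_identity_and_reversal(self):
        tai = compute_tai(load_tai_parameters())["tai"]
        rho, _ = occupancy_tai_correlation(self._profile_from(1.0 / tai), tai)
        assert rho == pytest.approx(1.0)
        rho, _ = occupancy_tai_correlation(self._profile_from(tai.copy()), tai)
        assert rho == pytest.approx(-1.0)

    def test_too_few_codons_rejected(self):
        tai = compute_tai(load_tai_parameters())["tai"]
        small = self._profile_from((1.0 / tai).iloc[:5])
        with pytest.raises(ValueError):
            occupancy_tai_correlation(small, tai.iloc[:5])


class TestEnrichmentProfile:
    def test_flat_dwell_near_unity_and_target_recovery(self):
        tx = generate_transcriptome(20, (150, 250), seed=81, abundance_sigma=0.0)
        sim = simulate_footprints(tx, DwellConfig({"AGG": 3.0}), depth=60000, seed=81)
        asites = truth_to_asites(tx, sim.truth)
        prof = relative_enrichment_profile(asites, tx, ["AGG"], max_offset=30)
        at0 = prof.loc["AGG", 0]
        # proportions normalization damps the raw multiplier slightly
        f = 1 / 61
        expected = 3.0 / (1 + 2 * f)
        assert at0 == pytest.approx(expected, rel=0.1)
        off_target = prof.loc["AGG"].drop(0).dropna()
        inner = off_target[np.abs(off_target.index) <= 20]
        assert (inner - 1 / (1 + 2 * f)).abs().max() < 0.25

    def test_offset_zero_matches_occupancy_same_normalizer(self, small_tx):
        sim = simulate_footprints(small_tx, depth=3000, seed=82)
        asites = truth_to_asites(small_tx, sim.truth)
        prof = relative_enrichment_profile(asites, small_tx, ["GAC", "AAA"], max_offset=5)
        # recompute occupancy with the profile's own offset-0 background
        gene_reads = asites.groupby("gene_id").size()
        counts: dict[str, float] = {}
        for gene, n in gene_reads.items():
            t = small_tx.get(gene)
            for c in t.codons[:-1]:
                counts[c] = counts.get(c, 0.0) + n / (t.n_codons - 1)
        usage = pd.Series(0.0, index=list(SENSE_CODONS))
        for c, v in counts.items():
            usage[c] = v
        usage /= usage.sum()
        occ = bulk_codon_occupancy(asites, usage, min_count=1).occupancy
        for codon in ("GAC", "AAA"):
            assert prof.loc[codon, 0] == pytest.approx(occ[codon], rel=1e-9)

    def test_offsets_beyond_cds_missing(self):
        t = Transcript("tiny", "ATG" + "AAA" * 10 + "TAA")
        tx = TranscriptomeFixture([t])
        asites = make_asites([("r0", "tiny", 5, "AAA")])
        prof = relative_enrichment_profile(asites, tx, ["AAA"], max_offset=30)
        assert np.isnan(prof.loc["AAA", 25])
        assert np.isnan(prof.loc["AAA", -25])
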