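"""Filtering, incorporation, normalization, and protein aggregation."""

from __future__ import annotations

import numpy as np
import pytest

from silaf import (
    EvidenceRow,
    ProteinGroupRow,
    filter_protein_groups,
    incorporation_rate,
    incorporation_timecourse,
    normalize_ratios,
    quantify_comparison,
)
from silaf.quant_core import pooled_incorporation_by_timepoint
from silaf.runlog import RunLog


def _group(gid, **flags):
    return ProteinGroupRow(protein_group_id=gid, member_protein_ids=(gid,), **flags)


class TestFilterProteinGroups:
    def test_single_flagged_row_removed(self):
        rows = [_group("A"), _group("B"), _group("C"), _group("D"),
                _group("R", flag_reverse=True)]
        assert [g.protein_group_id for g in filter_protein_groups(rows)] == \
            ["A", "B", "C", "D"]

    def test_doubly_flagged_row_counted_under_both_flags(self):
        log = RunLog()
        rows = [_group("A"), _group("X", flag_reverse=True, flag_contaminant=True)]
        kept = filter_protein_groups(rows, log)
        assert len(kept) == 1
        (event,) = [e for e in log.events if e["event"] == "filter_protein_groups"]
        assert event["n_reverse"] == 1 and event["n_contaminant"] == 1
        assert event["n_kept"] == 1

    def test_all_clean_input_is_identity(self):
        rows = [_group(f"P{i}") for i in range(5)]
        assert filter_protein_groups(rows) == rows

    def test_no_flagged_row_survives_no_clean_row_lost(self):
        rng = np.random.default_rng(0)
        rows = [_group(f"P{i}",
                       flag_reverse=bool(rng.random() < 0.3),
                       flag_contaminant=bool(rng.random() < 0.3),
                       flag_only_by_site=bool(rng.random() < 0.3))
                for i in range(200)]
        kept = filter_protein_groups(rows)
        clean = [r for r in rows if not (r.flag_reverse or r.flag_contaminant
                                         or r.flag_only_by_site)]
        assert kept == clean


class TestIncorporationRate:
    @pytest.mark.parametrize("h,l,expected", [
        (50, 50, 0.5), (1, 0, 1.0), (3, 1, 0.75), (0, 4, 0.0),
    ])
    def test_closed_form(self, h, l, expected):
        assert incorporation_rate(h, l) == pytest.approx(expected, abs=1e-15)

    def test_no_signal_is_missing_not_zero(self):
        assert np.isnan(incorporation_rate(0.0, 0.0))
        assert np.isnan(incorporation_rate(np.nan, np.nan))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            incorporation_rate(-1.0, 2.0)


class TestNormalizeRatios:
    def test_median_centering_contract(self):
        assert normalize_ratios([2, 2, 2]) == pytest.approx([1, 1, 1])

    def test_symmetric_ratios_unchanged(self):
        assert normalize_ratios([0.5, 1, 2]) == pytest.approx([0.5, 1, 2])

    def test_single_ratio_centered_to_one(self):
        assert normalize_ratios([8.0]) == pytest.approx([1.0])

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        ratios = rng.lognormal(0.3, 1.0, size=51)
        once = normalize_ratios(ratios)
        assert normalize_ratios(once) == pytest.approx(list(once), rel=1e-12)

    def test_scale_equivariance(self):
        """Multiplying all heavy intensities by c leaves normalized ratios unchanged."""
        rng = np.random.default_rng(2)
        ratios = rng.lognormal(0.0, 0.7, size=33)
        for c in (0.1, 7.0, 1e4):
            scaled = normalize_ratios(ratios * c)
            assert scaled == pytest.approx(list(normalize_ratios(ratios)), rel=1e-9)

    def test_no_finite_ratio_is_an_error_naming_the_run(self):
        with pytest.raises(ValueError, match="run7"):
            normalize_ratios([np.nan, 0.0], run="run7")


def _ev(seq, h, light, pid="P1", run="r1", bio=1, tech=1, t=None):
    return EvidenceRow(peptide_sequence=seq, charge=2, intensity_heavy=h,
                       intensity_light=light, protein_group_id=pid, raw_file=run,
                       replicate_bio=bio, replicate_tech=tech, timepoint_days=t)


class TestQuantifyComparison:
    def test_protein_ratio_is_median_of_peptide_ratios(self):
        # log2 ratios 1, 1, 3 -> median 1; another protein supplies the
        # median-centering anchor at ratio 1 so the shift is 0
        anchors = [_ev(f"ANCHR{'A' * i}K", 10, 10, pid="P0") for i in range(5)]
        ev = anchors + [_ev("AAK", 20, 10), _ev("CCK", 20, 10), _ev("DDK", 80, 10)]
        groups = [_group("P0"), _group("P1")]
        q = quantify_comparison(ev, groups)
        assert q.summary.loc["P1", "mean_log2fc"] == pytest.approx(1.0, abs=1e-12)
        assert q.summary.loc["P1", "n_peptide_ratios"] == 3

    def test_single_peptide_protein_keeps_its_value(self):
        ev = [_ev(f"A{'C' * i}K", 10, 10, pid="P0") for i in range(3)] + \
             [_ev("WWK", 40, 10, pid="P1")]
        q = quantify_comparison(ev, [_group("P0"), _group("P1")])
        assert q.summary.loc["P1", "mean_log2fc"] == pytest.approx(2.0, abs=1e-12)

    def test_technical_replicates_averaged_before_biology(self):
        # bio 1 has tech ratios 2 and 8 (log2 1 and 3 -> bio value 2);
        # bio 2 has a single tech ratio 4 (log2 2)
        ev = []
        for bio, tech, ratio in [(1, 1, 2.0), (1, 2, 8.0), (2, 1, 4.0)]:
            run = f"r{bio}{tech}"
            ev += [_ev(f"AN{'A' * i}K", 10, 10, pid="P0", run=run, bio=bio, tech=tech)
                   for i in range(3)]
            ev.append(_ev("WWK", 10 * ratio, 10, pid="P1", run=run, bio=bio, tech=tech))
        q = quantify_comparison(ev, [_group("P0"), _group("P1")])
        assert q.per_bio.loc["P1", "bio1"] == pytest.approx(2.0, abs=1e-12)
        assert q.per_bio.loc["P1", "bio2"] == pytest.approx(2.0, abs=1e-12)
        assert q.summary.loc["P1", "mean_log2fc"] == pytest.approx(2.0, abs=1e-12)

    def test_flagged_groups_never_quantified(self):
        ev = [_ev("AAK", 10, 10, pid="P0"), _ev("CCK", 10, 10, pid="CON__1")]
        q = quantify_comparison(ev, [_group("P0"), _group("CON__1", flag_contaminant=True)])
        assert "CON__1" not in q.summary.index

    def test_one_channel_only_rows_excluded_from_ratios(self):
        ev = [_ev(f"A{'C' * i}K", 10, 10, pid="P0") for i in range(3)] + \
             [_ev("WWK", 40, 10, pid="P1"), _ev("YYK", 99, None, pid="P1")]
        q = quantify_comparison(ev, [_group("P0"), _group("P1")])
        assert q.summary.loc["P1", "n_peptide_ratios"] == 1
        assert q.summary.loc["P1", "mean_log2fc"] == pytest.approx(2.0, abs=1e-12)


class TestIncorporationTimecourse:
    def test_fully_labeled_protein(self):
        ev = [_ev("AAK", 60, 0.0, t=2.0), _ev("CCK", 40, 0.0, t=2.0)]
        tc = incorporation_timecourse(ev)
        assert tc["fraction"].tolist() == [1.0]

    def test_half_labeled(self):
        ev = [_ev("AAK", 50, 50, t=2.0)]
        tc = incorporation_timecourse(ev)
        assert tc["fraction"].iloc[0] == pytest.approx(0.5, abs=1e-15)

    def test_intensity_weighted_sum_before_ratio(self):
        # peptides 90/10 and 10/90: intensity-weighted fraction is 0.5,
        # not the mean of the per-peptide fractions
        ev = [_ev("AAK", 90, 10, t=1.0), _ev("CCK", 10, 90, t=1.0)]
        tc = incorporation_timecourse(ev)
        assert tc["fraction"].iloc[0] == pytest.approx(0.5, abs=1e-15)

    def test_noise_free_pooled_median_matches_closed_form(self):
        """A k = 0.75/day proteome observed noise-free at t = 6 days pools to
        a median fraction of 1 - e^(-4.5)."""
        import dataclasses
        from silaf import ExperimentDesign, NoiseModel, make_ground_truth, simulate_tables
        gt = make_ground_truth(
            n_proteins=20, seed=8, noise=NoiseModel.noise_free(),
            design=ExperimentDesign(mode="timecourse", n_bio=2,
                                    timepoints_days=(0.0, 6.0),
                                    contaminant_rate=0, decoy_rate=0))
        proteins = tuple(dataclasses.replace(p, turnover_rate_k=0.75)
                         for p in gt.proteins)
        gt = dataclasses.replace(gt, proteins=proteins)
        ev, pg, _ = simulate_tables(gt)
        tc = incorporation_timecourse(ev, pg)
        pooled = pooled_incorporation_by_timepoint(tc)
        assert pooled.loc[6.0, "median"] == pytest.approx(1 - np.exp(-4.5), abs=1e-9)

    def test_monotone_in_time_for_noise_free_simulation(self):
        from silaf import ExperimentDesign, NoiseModel, make_ground_truth, simulate_tables
        gt = make_ground_truth(
            n_proteins=10, seed=12, noise=NoiseModel.noise_free(),
            design=ExperimentDesign(mode="timecourse", n_bio=1,
                                    contaminant_rate=0, decoy_rate=0))
        ev, pg, _ = simulate_tables(gt)
        tc = incorporation_timecourse(ev, pg)
        for _pid, grp in tc.groupby("protein_group_id"):
            fracs = grp.sort_values("timepoint")["fraction"].to_numpy()
            assert np.all(np.diff(fracs) >= -1e-12)

    def test_no_timecourse_evidence_is_an_error(self):
        with pytest.raises(ValueError, match="time"):
            incorporation_timecourse([_ev("AAK", 1, 1)])

    def test_pool_before_sums_across_replicates(self):
        ev = [_ev("AAK", 90, 10, t=1.0, bio=1), _ev("AAK", 10, 90, t=1.0, bio=2)]
        after = incorporation_timecourse(ev, pool_replicates="after")
        before = incorporation_timecourse(ev, pool_replicates="before")
        assert sorted(after["fraction"]) == pytest.approx([0.1, 0.9])
        assert before["fraction"].tolist() == pytest.approx([0.5])
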