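"""Composite regulon calling: filters, rescue, union, curation, timing."""

import numpy as np
import pandas as pd
import pytest

from regulonkit import targets
from regulonkit.pipeline import call_depletion_regulon
from regulonkit.quantio import ChipScoreTable, SampleSheet
from regulonkit.synthetic import STAGES


def _de(rows):
    """rows: gene -> (padj, log2FC)"""
    return pd.DataFrame(
        [{"gene_id": g, "padj": p, "log2FC": l} for g, (p, l) in rows.items()])


class TestBaselineFilter:
    def test_flagged_gene_removed(self):
        neg30 = _de({"A": (0.5, 0.1), "B": (0.9, 0.0), "C": (0.7, 0.2)})
        t0 = _de({"A": (0.6, 0.2), "B": (0.01, 1.2), "C": (0.8, 0.1)})
        assert targets.filter_baseline_de(["A", "B", "C"], neg30, t0) == ["A", "C"]

    def test_boundary_lfc_exactly_one_retained(self):
        neg30 = _de({"A": (0.01, 1.0)})
        t0 = _de({"A": (0.01, 1.0)})
        assert targets.filter_baseline_de(["A"], neg30, t0) == ["A"]

    def test_no_flags_is_identity_and_or_semantics(self):
        neg30 = _de({"A": (0.01, 2.0), "B": (0.9, 0.0)})
        t0 = _de({"A": (0.9, 0.0), "B": (0.9, 0.0)})
        # A flagged at -30 only: OR semantics removes it
        assert targets.filter_baseline_de(["A", "B"], neg30, t0) == ["B"]
        clean = _de({"A": (0.9, 0.0), "B": (0.9, 0.0)})
        assert targets.filter_baseline_de(["A", "B"], clean, clean) == ["A", "B"]

    def test_missing_candidate_is_lookup_error(self):
        de = _de({"A": (0.5, 0.1)})
        with pytest.raises(KeyError):
            targets.filter_baseline_de(["A", "zzz"], de, de)


class TestAcuteFilter:
    @pytest.mark.parametrize("padj,lfc,kept", [
        (0.03, 0.5, True),
        (0.2, 0.5, False),
        (0.01, 0.3, False),   # boundary: strict >
        (0.01, -0.31, True),  # absolute value
    ])
    def test_rule(self, padj, lfc, kept):
        de = _de({"A": (padj, lfc)})
        assert targets.filter_acute_response(["A"], de) == (["A"] if kept else [])


class TestTpmRescue:
    @pytest.fixture()
    def tiny_tpm(self):
        tps = [15, 30, 60, 120]
        rows, cols = {}, []
        sheet_rows = []
        for cond in ("control", "depletion"):
            for t in tps:
                sid = f"{cond}_{t}_1"
                cols.append(sid)
                sheet_rows.append({"sample_id": sid, "condition": cond,
                                   "timepoint": t, "replicate": 1})
        sheet = SampleSheet(pd.DataFrame(sheet_rows))
        return cols, sheet

    def _tpm_for_ratios(self, cols, ratios):
        """Build TPM with control fixed at 99 and depletion realizing ratios."""
        control = 99.0
        vals = {}
        for c in cols:
            cond, t, _ = c.split("_")
            if cond == "control":
                vals[c] = [control]
            else:
                r = ratios[int(t)]
                vals[c] = [r * (control + 1.0) - 1.0]
        return pd.DataFrame(vals, index=["g"])

    def test_rescued_up(self, tiny_tpm):
        cols, sheet = tiny_tpm
        tpm = self._tpm_for_ratios(cols, {15: 1.5, 30: 1.3, 60: 1.6, 120: 1.4})
        out = targets.tpm_ratio_rescue(tpm, sheet)
        assert out.loc["g", "avg_ratio"] == pytest.approx(1.45)
        assert bool(out.loc["g", "rescued"])

    def test_flat_not_rescued(self, tiny_tpm):
        cols, sheet = tiny_tpm
        tpm = self._tpm_for_ratios(cols, {t: 1.0 for t in (15, 30, 60, 120)})
        assert not bool(targets.tpm_ratio_rescue(tpm, sheet)["rescued"].iloc[0])

    def test_boundary_inclusive(self, tiny_tpm):
        cols, sheet = tiny_tpm
        tpm = self._tpm_for_ratios(cols, {t: 1.4 for t in (15, 30, 60, 120)})
        assert bool(targets.tpm_ratio_rescue(tpm, sheet)["rescued"].iloc[0])
        tpm = self._tpm_for_ratios(cols, {t: 0.6 for t in (15, 30, 60, 120)})
        assert bool(targets.tpm_ratio_rescue(tpm, sheet)["rescued"].iloc[0])

    def test_missing_timepoint_errors(self, tiny_tpm):
        cols, sheet = tiny_tpm
        tpm = self._tpm_for_ratios(cols, {t: 1.0 for t in (15, 30, 60, 120)})
        with pytest.raises(KeyError):
            targets.tpm_ratio_rescue(tpm, sheet, timepoints=(15, 30, 60, 120, 240))


class TestComposite:
    def test_printed_set_algebra_165(self):
        a = [f"d{i}" for i in range(135)]
        b = a[:98] + [f"t{i}" for i in range(30)]
        assert len(b) == 128
        comp = targets.build_composite(a, b)
        assert len(comp) == 165
        assert (comp["source"] == "both").sum() == 98
        assert (comp["source"] == "tpm_path").sum() == 30

    def test_source_labels(self):
        comp = targets.build_composite(["g1", "g2"], ["g2", "g3"])
        assert comp["source"].to_dict() == {
            "g1": "deseq_path", "g2": "both", "g3": "tpm_path"}

    def test_subset_is_identity_and_commutative_membership(self):
        comp = targets.build_composite(["g1", "g2"], ["g2"])
        assert list(comp.index) == ["g1", "g2"]
        ab = set(targets.build_composite(["a", "b"], ["c"]).index)
        ba = set(targets.build_composite(["c"], ["a", "b"]).index)
        assert ab == ba


class TestChipCuration:
    def _chip(self):
        scores = pd.DataFrame({"rep1": [4.0, 8.0, 3.9], "rep2": [5.0, 10.0, 4.9],
                               "rep3": [6.0, 12.0, 5.9]},
                              index=pd.Index(["gA", "ref", "gB"], name="gene_id"))
        return ChipScoreTable(scores, "ref")

    def test_inclusive_boundary_and_self_ratio(self):
        comp = targets.build_composite(["gA", "ref", "gB"], [])
        out = targets.chip_curation(comp, self._chip())
        assert out.loc["gA", "chip_ratio"] == pytest.approx(0.5)
        assert bool(out.loc["gA", "direct"])          # ratio 0.5 inclusive
        assert out.loc["ref", "chip_ratio"] == pytest.approx(1.0)
        assert not bool(out.loc["gB", "direct"])      # 0.49 fails

    def test_monotone_in_threshold(self):
        comp = targets.build_composite(["gA", "ref", "gB"], [])
        lo = targets.chip_curation(comp, self._chip(), threshold=0.4)
        hi = targets.chip_curation(comp, self._chip(), threshold=0.6)
        assert set(hi.index[hi["direct"]]) <= set(lo.index[lo["direct"]])

    def test_missing_gene_listed(self):
        comp = targets.build_composite(["gA", "nope"], [])
        with pytest.raises(KeyError, match="nope"):
            targets.chip_curation(comp, self._chip())


class TestClassifyTiming:
    def _atlas(self, rows):
        return pd.DataFrame(rows, columns=list(STAGES))

    def test_argmax_and_tie_break(self):
        atlas = self._atlas([[5, 2, 1, 0, 0], [5, 5, 0, 0, 0], [0, 1, 9, 2, 0]])
        atlas.index = ["gA", "gB", "gC"]
        stages, counts = targets.classify_timing(["gA", "gB", "gC"], atlas)
        assert stages["gA"] == "meiotic entry"
        assert stages["gB"] == "meiotic entry"   # tie -> earliest stage
        assert stages["gC"] == "recombination"
        assert counts["emg"] == 3

    def test_emg_rollup_printed_counts(self):
        rows = ([[9, 0, 0, 0, 0]] * 49 + [[0, 9, 0, 0, 0]] * 12
                + [[0, 0, 9, 0, 0]] * 66 + [[0, 0, 0, 9, 0]] * 17)
        atlas = self._atlas(rows)
        atlas.index = [f"g{i}" for i in range(len(rows))]
        _, counts = targets.classify_timing(list(atlas.index), atlas)
        assert counts["emg"] == 127
        assert (counts["meiotic entry"], counts["DNA replication"],
                counts["recombination"]) == (49, 12, 66)

    def test_missing_gene_errors(self):
        atlas = self._atlas([[1, 0, 0, 0, 0]])
        atlas.index = ["gA"]
        with pytest.raises(KeyError):
            targets.classify_timing(["gA", "gB"], atlas)


@pytest.fixture(scope="module")
def result(depletion_experiment, chip_and_atlas):
    counts, sheet, gene_table, _ = depletion_experiment
    chip, atlas, truth = chip_and_atlas
    res = call_depletion_regulon(counts, sheet, gene_table, chip, atlas)
    return res, truth


class TestEndToEndRecovery:
    """Planted-truth recovery through the whole composite procedure."""

    def test_direct_targets_recovered(self, result):
        res, truth = result
        direct = set(truth.index[truth["class"] == "direct"])
        recovered = direct & set(res["direct"])
        assert len(recovered) / len(direct) >= 0.90

    def test_confounded_removed_at_baseline(self, result):
        res, truth = result
        confounded = set(truth.index[truth["class"] == "confounded"])
        series = res["series"].set_index("gene_id")
        candidates = set(series.index[series["padj"] < 0.05]) & confounded
        survivors = confounded & set(
            res["calls"].index[res["calls"]["source"] != "tpm_path"])
        assert len(candidates) > 0
        assert 1 - len(survivors) / len(candidates) >= 0.95

    def test_slow_responders_rescued_on_tpm_path_only(self, result):
        res, truth = result
        slow = set(truth.index[truth["class"] == "slow"])
        calls = res["calls"]
        on_tpm_only = {g for g in slow if g in calls.index
                       and calls.loc[g, "source"] == "tpm_path"}
        assert len(on_tpm_only) / len(slow) >= 0.80

    def test_no_nulls_in_final_direct_list(self, result):
        res, truth = result
        nulls = set(truth.index[truth["class"] == "null"])
        assert len(nulls & set(res["direct"])) == 0

    def test_bookkeeping_arithmetic(self, result):
        res, _ = result
        s = res["sizes"]
        assert s["composite"] == (s["after_acute_filter"] + s["tpm_rescued"]
                                  - s["rescue_overlap"])
        assert s["direct"] <= s["composite"]
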