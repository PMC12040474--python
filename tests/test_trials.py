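"""Trial I/O, aggregation and exclusion tests."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recalib.simulate import DesignSpec, GeneratorConfig, generate_dataset, paper_like_group
from recalib.trials import (
    FRAME_MS,
    aggregate,
    bin_to_frames,
    exclusion_filter,
    load_trials,
    table_to_celldata,
)

HEADER = "participant_id,task,modality,lag,rsa_ms,response\n"


def _load_str(text, **kw):
    return load_trials(io.StringIO(text), **kw)


class TestLoadTrials:
    def test_valid_rows_pass_through(self):
        csv = HEADER + (
            "p1,simultaneity,visual,lag0,100,yes\n"
            "p1,Agency,AUDITORY,lag150,-66.7,no\n"
            "p2,simultaneity,visual,lag0,0,1\n"
        )
        df, report = _load_str(csv)
        assert len(df) == 3 and report.n_rejected == 0
        assert list(df["response"]) == [1, 0, 1]
        assert df["task"].tolist() == ["simultaneity", "agency", "simultaneity"]

    def test_invalid_level_collected_with_line_number(self):
        csv = HEADER + "p1,simultaneity,visual,lag0,100,maybe\np1,agency,visual,lag0,50,yes\n"
        df, report = _load_str(csv, max_reject_fraction=0.9)
        assert len(df) == 1
        assert report.n_rejected == 1
        assert "line 2" in report.errors[0] and "maybe" in report.errors[0]

    def test_missing_column_fatal(self):
        with pytest.raises(ValueError, match="response"):
            _load_str("participant_id,task,modality,lag,rsa_ms\np1,a,v,l,1\n")

    def test_too_many_rejections_fatal(self):
        csv = HEADER + "p1,bad,bad,bad,x,zz\n" * 3 + "p1,agency,visual,lag0,50,yes\n"
        with pytest.raises(ValueError, match="rejected"):
            _load_str(csv)

    def test_generator_roundtrip_lossless(self, tmp_path):
        trials, _ = generate_dataset(
            GeneratorConfig(group=paper_like_group(), n_participants=2, seed=7)
        )
        path = tmp_path / "trials.csv"
        trials.to_csv(path, index=False)
        back, report = load_trials(path)
        assert report.n_rejected == 0
        pd.testing.assert_frame_equal(
            back.sort_values(list(back.columns)).reset_index(drop=True),
            trials.sort_values(list(trials.columns)).reset_index(drop=True),
            check_dtype=False,
        )


class TestAggregate:
    def test_counts(self):
        df = pd.DataFrame(
            {
                "participant_id": ["p1"] * 10,
                "task": ["agency"] * 10,
                "modality": ["visual"] * 10,
                "lag": ["lag0"] * 10,
                "rsa_ms": [100.0] * 10,
                "response": [1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
            }
        )
        tab = aggregate(df)
        assert len(tab) == 1
        assert tab.iloc[0]["n_trials"] == 10 and tab.iloc[0]["n_yes"] == 4

    def test_frame_binning_merges_neighbouring_negative_rsas(self):
        df = pd.DataFrame(
            {
                "participant_id": ["p1", "p1"],
                "task": ["agency"] * 2,
                "modality": ["visual"] * 2,
                "lag": ["lag0"] * 2,
                "rsa_ms": [-100.1, -99.9],
                "response": [1, 0],
            }
        )
        tab = aggregate(df)  # default: negative RSAs snap to 120 Hz frames
        assert len(tab) == 1
        expected = round(-100.1 / FRAME_MS) * FRAME_MS
        assert tab.iloc[0]["rsa_ms"] == pytest.approx(expected, abs=1e-6)
        assert tab.iloc[0]["n_trials"] == 2 and tab.iloc[0]["n_yes"] == 1

    def test_exact_mode_keeps_values(self):
        df = pd.DataFrame(
            {
                "participant_id": ["p1", "p1"],
                "task": ["agency"] * 2,
                "modality": ["visual"] * 2,
                "lag": ["lag0"] * 2,
                "rsa_ms": [-100.1, -99.9],
                "response": [1, 0],
            }
        )
        assert len(aggregate(df, rsa_binning="exact")) == 2

    def test_empty_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate(pd.DataFrame(columns=["participant_id", "task", "modality",
                                            "lag", "rsa_ms", "response"]))

    def test_trial_conservation_and_proportions(self, small_cohort):
        tab = small_cohort["table"]
        assert tab["n_trials"].sum() == len(small_cohort["trials"])
        prop = tab["n_yes"] / tab["n_trials"]
        assert ((prop >= 0) & (prop <= 1)).all()

    @given(seed=st.integers(0, 2**16))
    @settings(deadline=None, derandomize=True, max_examples=10)
    def test_order_invariance(self, seed):
        trials, _ = generate_dataset(
            GeneratorConfig(
                group=paper_like_group(),
                n_participants=2,
                design=DesignSpec(reps_per_rsa=2),
                seed=5,
            )
        )
        shuffled = trials.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        pd.testing.assert_frame_equal(aggregate(trials), aggregate(shuffled))

    def test_reaggregation_idempotent(self, small_cohort, tmp_path):
        tab = small_cohort["table"]
        path = tmp_path / "table.csv"
        tab.to_csv(path, index=False)
        back = pd.read_csv(path)
        # expanding cells to unit trials and re-aggregating restores counts
        rows = back.loc[back.index.repeat(back["n_trials"])].copy()
        grp = rows.groupby(["participant_id", "task", "modality", "lag", "rsa_ms"])
        rows["response"] = (grp.cumcount() < rows["n_yes"]).astype(int)
        again = aggregate(rows[["participant_id", "task", "modality", "lag",
                                "rsa_ms", "response"]], rsa_binning="exact")
        pd.testing.assert_frame_equal(
            again.reset_index(drop=True), tab.reset_index(drop=True),
            check_dtype=False,
        )


class TestBinToFrames:
    @given(rsa=st.floats(-500, 500))
    @settings(deadline=None, derandomize=True)
    def test_round_to_nearest_frame(self, rsa):
        out = bin_to_frames(rsa)
        assert abs(out - rsa) <= FRAME_MS / 2 + 1e-9
        assert abs(out / FRAME_MS - round(out / FRAME_MS)) < 1e-9


class TestExclusionFilter:
    def _trials(self, yes_frac_agency):
        n = 200
        n_yes = int(round(yes_frac_agency * n))
        return pd.DataFrame(
            {
                "participant_id": ["p1"] * (2 * n),
                "task": ["agency"] * n + ["simultaneity"] * n,
                "modality": ["visual"] * (2 * n),
                "lag": ["lag0"] * (2 * n),
                "rsa_ms": [100.0] * (2 * n),
                "response": [1] * n_yes + [0] * (n - n_yes) + [1] * (n // 2) + [0] * (n - n // 2),
            }
        )

    def test_low_yes_task_dropped_other_kept(self):
        kept, report = exclusion_filter(self._trials(0.01))
        assert set(kept["task"]) == {"simultaneity"}
        assert report.removed[0]["task"] == "agency"
        assert report.removed[0]["yes_fraction"] == pytest.approx(0.01)

    def test_all_above_threshold_noop(self):
        trials = self._trials(0.5)
        kept, report = exclusion_filter(trials)
        assert len(kept) == len(trials) and report.removed == []

    def test_zero_threshold_vacuous(self):
        trials = self._trials(0.0)
        kept, _ = exclusion_filter(trials, min_yes_fraction=0.0)
        assert len(kept) == len(trials)

    def test_bad_threshold_fatal(self):
        with pytest.raises(ValueError):
            exclusion_filter(self._trials(0.5), min_yes_fraction=1.5)


class TestTableToCellData:
    def test_shapes_and_invariants(self, small_cohort):
        cells = small_cohort["cells"]
        assert len(cells) == 5
        tab = small_cohort["table"]
        total = sum(c.n.sum() for c in cells.values())
        assert total == tab["n_trials"].sum()
        for c in cells.values():
            assert np.all(c.y <= c.n)
            assert np.all((c.cond_idx >= 0) & (c.cond_idx < 8))
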