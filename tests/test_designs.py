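"""Structure and transition-probability properties of generated sequences."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import slonline as sl
from slonline.designs import _cycle_ok


def _chunk_seq(frame):
    """Chunk order of a structured frame (consecutive duplicates collapsed)."""
    d = frame[frame["phase"] == "structured"]
    ids = d["chunk_id"].tolist()
    out = [ids[0]]
    for c in ids[1:]:
        if c != out[-1]:
            out.append(c)
    return out


class TestInventories:
    def test_exp1a_inventory(self, rng):
        chunks = sl.make_chunks(sl.EXP1A, rng)
        assert len(chunks) == 8
        pairs = [c for c in chunks if c.kind == "pair"]
        singles = [c for c in chunks if c.kind == "single"]
        assert len(pairs) == 4 and len(singles) == 4
        # all pairs category-alternating, two per direction
        cats = sorted(p.categories for p in pairs)
        assert cats == [("A", "B"), ("A", "B"), ("B", "A"), ("B", "A")]
        stimuli = [s for c in chunks for s in c.stimuli]
        assert len(set(stimuli)) == 12

    def test_exp1b_inventory_has_repeating_pairs(self, rng):
        chunks = sl.make_chunks(sl.EXP1B, rng)
        cats = sorted(c.categories for c in chunks if c.kind == "pair")
        assert cats == [("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")]

    def test_exp2_inventory(self, rng):
        chunks = sl.make_chunks(sl.EXP2, rng)
        assert len(chunks) == 12
        assert sum(c.kind == "single" for c in chunks) == 8
        assert len({s for c in chunks for s in c.stimuli}) == 16

    def test_category_balance(self, rng):
        for spec in (sl.EXP1A, sl.EXP1B, sl.EXP2):
            chunks = sl.make_chunks(spec, rng)
            cats = [c for ch in chunks for c in ch.categories]
            assert cats.count("A") == cats.count("B")

    def test_imbalanced_spec_rejected(self):
        with pytest.raises(sl.ConfigurationError):
            sl.DesignSpec(
                name="bad",
                pair_templates=(("A", "A"),),
                n_pairs=1,
                n_singles_per_category=1,
                n_cycles=2,
                warmup_cycles=0,
                juncture_min_gap=0,
                pair_followed_by_single=False,
                n_runs=1,
                iti_ms=(500.0, 500.0),
            )


class TestRunStructure:
    def test_exp1a_run_has_72_trials(self, exp1a_run_frame):
        frame, _ = exp1a_run_frame
        assert len(frame) == 72
        assert (frame["phase"] == "structured").all()

    def test_exp2_run_400_trials_160_warmup(self, exp2_run_frame):
        frame, _ = exp2_run_frame
        assert len(frame) == 400
        assert (frame["phase"] == "warmup").sum() == 160
        assert (frame["phase"] == "structured").sum() == 240
        warm = frame[frame["phase"] == "warmup"]
        assert (warm["condition"] == "RANDOM").all()
        assert (warm["repetition"] == 0).all()

    @pytest.mark.parametrize("spec", [sl.EXP1A, sl.EXP1B, sl.EXP2], ids=lambda s: s.name)
    def test_each_chunk_once_per_cycle(self, spec, rng):
        chunks = sl.make_chunks(spec, rng)
        frame = sl.trials_to_frame(sl.generate_run(spec, chunks, rng))
        d = frame[frame["phase"] == "structured"]
        size_of = {c.chunk_id: len(c.stimuli) for c in chunks}
        per_cycle = d.groupby(["repetition", "chunk_id"]).size()
        for (_, cid), n_trials in per_cycle.items():
            assert n_trials == size_of[cid]  # chunk appears exactly once
        assert set(per_cycle.index.get_level_values("repetition")) == set(
            range(1, spec.n_cycles + 1)
        )
        # every chunk appears n_cycles times in total (trials = size x cycles)
        for cid, n_trials in d["chunk_id"].value_counts().items():
            assert n_trials == spec.n_cycles * size_of[cid]

    @pytest.mark.parametrize("spec", [sl.EXP1A, sl.EXP2], ids=lambda s: s.name)
    def test_pairs_contiguous_in_order(self, spec, rng):
        chunks = sl.make_chunks(spec, rng)
        frame = sl.trials_to_frame(sl.generate_run(spec, chunks, rng))
        d = frame[frame["phase"] == "structured"].reset_index(drop=True)
        p1_rows = d.index[d["condition"] == "P1"]
        pair_map = {c.chunk_id: c for c in chunks if c.kind == "pair"}
        for i in p1_rows:
            ch = pair_map[d.loc[i, "chunk_id"]]
            assert d.loc[i, "stimulus_id"] == ch.stimuli[0]
            assert d.loc[i + 1, "stimulus_id"] == ch.stimuli[1]
            assert d.loc[i + 1, "condition"] == "P2"

    def test_single_cycle_no_warmup(self, rng):
        from dataclasses import replace

        spec = replace(sl.EXP1A, n_cycles=1, name="custom")
        chunks = sl.make_chunks(spec, rng)
        frame = sl.trials_to_frame(sl.generate_run(spec, chunks, rng))
        assert len(frame) == 12
        assert (frame["repetition"] == 1).all()
        assert sorted(frame["chunk_id"].unique()) == sorted(
            c.chunk_id for c in chunks
        )

    def test_juncture_constraint_sliding_window(self, rng):
        """No stimulus recurs before 3 distinct others intervened."""
        for spec in (sl.EXP1A, sl.EXP1B):
            chunks = sl.make_chunks(spec, rng)
            for _ in range(20):
                frame = sl.trials_to_frame(sl.generate_run(spec, chunks, rng))
                seq = frame["stimulus_id"].tolist()
                last_seen = {}
                for t, s in enumerate(seq):
                    if s in last_seen:
                        between = set(seq[last_seen[s] + 1 : t]) - {s}
                        assert len(between) >= 3, f"{spec.name}: gap violated at {t}"
                    last_seen[s] = t

    def test_exp2_pair_followed_by_single(self, rng):
        chunks = sl.make_chunks(sl.EXP2, rng)
        singles = {c.chunk_id for c in chunks if c.kind == "single"}
        for _ in range(10):
            frame = sl.trials_to_frame(sl.generate_run(sl.EXP2, chunks, rng))
            seq = _chunk_seq(frame)
            for cur, nxt in zip(seq, seq[1:]):
                if cur.startswith("pair"):
                    assert nxt in singles

    def test_warmup_no_immediate_repeat(self, exp2_run_frame):
        frame, _ = exp2_run_frame
        seq = frame["stimulus_id"].tolist()
        assert all(a != b for a, b in zip(seq, seq[1:]))

    def test_generation_error_reports_constraint(self, rng):
        from dataclasses import replace

        # a gap that can never be satisfied across junctures of 2 stimuli
        spec = replace(
            sl.EXP1A,
            name="custom",
            n_pairs=1,
            n_singles_per_category=0,
            juncture_min_gap=5,
            pair_templates=(("A", "B"),),
        )
        chunks = sl.make_chunks(spec, rng)
        with pytest.raises(sl.GenerationError, match="juncture"):
            sl.generate_run(spec, chunks, rng)


class TestSessions:
    def test_exp1a_session_96_distinct_stimuli(self):
        rng = np.random.default_rng(1)
        runs = sl.generate_session(sl.EXP1A, "subA", rng)
        assert len(runs) == 8
        frame = sl.trials_to_frame(runs)
        assert frame["stimulus_id"].nunique() == 96
        # disjoint across runs
        per_run = frame.groupby("run")["stimulus_id"].unique()
        seen = set()
        for ids in per_run:
            assert not (set(ids) & seen)
            seen |= set(ids)

    def test_exp2_session_32_distinct_stimuli(self):
        rng = np.random.default_rng(2)
        frame = sl.trials_to_frame(sl.generate_session(sl.EXP2, "subB", rng))
        assert frame["stimulus_id"].nunique() == 32
        assert frame["run"].nunique() == 2

    def test_single_run_session_equals_run(self):
        from dataclasses import replace

        spec = replace(sl.EXP1A, n_runs=1, name="custom")
        runs = sl.generate_session(spec, "subC", np.random.default_rng(3))
        assert len(runs) == 1 and len(runs[0]) == 72

    def test_determinism_bitwise(self, tmp_path):
        paths = []
        for k in range(2):
            frame = sl.trials_to_frame(
                sl.generate_session(sl.EXP2, "subD", np.random.default_rng(99))
            )
            p = tmp_path / f"run{k}.csv"
            sl.write_trials(frame, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestTransitionStats:
    def test_within_pair_probability_is_one(self, exp1a_run_frame, exp2_run_frame):
        for frame, _ in (exp1a_run_frame, exp2_run_frame):
            stats = sl.empirical_transition_stats(frame)
            assert stats.within_pair_prob == 1.0

    def test_empty_input_errors(self):
        frame = sl.trials_to_frame([])
        with pytest.raises(sl.ConfigurationError):
            sl.empirical_transition_stats(frame)

    def test_exp1a_other_case_one_seventh(self):
        """Mean specific-successor probability is exactly 1/7: chunk
        self-succession is impossible, so each chunk's successor mass is
        spread over the 7 other chunks."""
        rng = np.random.default_rng(4)
        frames = []
        for i in range(50):
            chunks = sl.make_chunks(sl.EXP1A, rng)
            frames.append(
                sl.trials_to_frame(
                    sl.generate_run(sl.EXP1A, chunks, rng, session_id=f"s{i}")
                )
            )
        stats = sl.empirical_transition_stats(pd.concat(frames, ignore_index=True))
        assert stats.other_case_prob == pytest.approx(1 / 7, abs=1e-12)

    def test_exp1a_category_repetition_below_exp1b(self):
        rng = np.random.default_rng(5)
        rates = {}
        for spec in (sl.EXP1A, sl.EXP1B):
            frames = []
            for i in range(100):
                chunks = sl.make_chunks(spec, rng)
                frames.append(
                    sl.trials_to_frame(
                        sl.generate_run(spec, chunks, rng, session_id=f"s{i}")
                    )
                )
            rates[spec.name] = sl.empirical_transition_stats(
                pd.concat(frames, ignore_index=True)
            ).category_repetition_rate
        # all-alternating pairs force fewer category repetitions: the
        # structural source of the motor confound
        assert rates["exp1a"] < rates["exp1b"] - 0.10


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    n_pairs=st.integers(1, 4),
    n_singles=st.integers(1, 4),
    n_cycles=st.integers(1, 4),
    seed=st.integers(0, 10_000),
)
def test_custom_design_invariants(n_pairs, n_singles, n_cycles, seed):
    """Any valid custom design yields cycles with each chunk exactly once
    and pairs never split."""
    spec = sl.DesignSpec(
        name="custom",
        pair_templates=(("A", "B"), ("B", "A")),
        n_pairs=2 * n_pairs,  # even count keeps categories balanced
        n_singles_per_category=n_singles,
        n_cycles=n_cycles,
        warmup_cycles=1,
        juncture_min_gap=min(2, n_singles),
        pair_followed_by_single=False,
        n_runs=1,
        iti_ms=(500.0, 900.0),
    )
    rng = np.random.default_rng(seed)
    chunks = sl.make_chunks(spec, rng)
    frame = sl.trials_to_frame(sl.generate_run(spec, chunks, rng))
    assert len(frame) == spec.n_trials_per_run
    d = frame[frame["phase"] == "structured"]
    size_of = {c.chunk_id: len(c.stimuli) for c in chunks}
    for cid, n_trials in d["chunk_id"].value_counts().items():
        assert n_trials == n_cycles * size_of[cid]
    stats = sl.empirical_transition_stats(frame)
    assert stats.within_pair_prob == 1.0
    assert (frame["iti_ms"].between(500.0, 900.0)).all()
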