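import numpy as np
import pytest

from igtbayes import (
    GroupDataset,
    ParticipantData,
    TrialRecord,
    block_proportions,
    build_traditional_scheme,
    draw_payoff,
    read_dataset,
    write_dataset,
)
from igtbayes.igt_task import _BlockShuffler, dataset_to_arrays


class TestTraditionalScheme:
    def test_rewards_per_trial(self, scheme):
        assert [scheme.reward_per_trial[k] for k in (1, 2, 3, 4)] == [
            100, 100, 50, 50
        ]

    def test_block_loss_totals(self, scheme):
        assert scheme.block_loss_total("A") == -1250
        assert scheme.block_loss_total("B") == -1250
        assert scheme.block_loss_total("C") == -250
        assert scheme.block_loss_total("D") == -250

    def test_loss_counts(self, scheme):
        assert [scheme.block_loss_count(k) for k in "ABCD"] == [5, 1, 5, 1]

    def test_block_net_outcomes(self, scheme):
        assert scheme.block_net_outcome("A") == -250
        assert scheme.block_net_outcome("B") == -250
        assert scheme.block_net_outcome("C") == 250
        assert scheme.block_net_outcome("D") == 250

    def test_deterministic(self):
        assert build_traditional_scheme() == build_traditional_scheme()


class TestDrawPayoff:
    def test_deck_a_reward(self, scheme):
        for pos in (1, 7, 23, 101):
            reward, _ = draw_payoff(scheme, "A", pos)
            assert reward == 100

    def test_deck_b_one_loss_per_block(self, scheme):
        payoffs = [draw_payoff(scheme, 2, i) for i in range(1, 11)]
        losses = [loss for _, loss in payoffs if loss != 0]
        assert len(losses) == 1
        assert sum(loss for _, loss in payoffs) == -1250

    def test_any_aligned_window_matches_block_totals(self, scheme):
        for deck in (1, 2, 3, 4):
            for block in range(3):
                losses = [
                    draw_payoff(scheme, deck, block * 10 + i)[1]
                    for i in range(1, 11)
                ]
                assert sum(losses) == scheme.block_loss_total(deck)

    def test_shuffle_preserves_multiset(self, scheme):
        shuffled = scheme.with_shuffle()
        for seed in (1, 2):
            dealer = _BlockShuffler(shuffled, np.random.default_rng(seed))
            losses = sorted(dealer.deal(4)[1] for _ in range(10))
            assert losses == sorted(
                draw_payoff(scheme, 4, i)[1] for i in range(1, 11)
            )

    def test_unknown_deck(self, scheme):
        with pytest.raises(ValueError, match="unknown deck"):
            draw_payoff(scheme, 5, 1)

    def test_position_must_be_positive(self, scheme):
        with pytest.raises(ValueError):
            draw_payoff(scheme, 1, 0)


def _participant(decks, rewards=None, losses=None, pid="p1"):
    n = len(decks)
    rewards = rewards or [100.0] * n
    losses = losses or [0.0] * n
    return ParticipantData(
        pid,
        [TrialRecord(i + 1, d, r, l)
         for i, (d, r, l) in enumerate(zip(decks, rewards, losses))],
    )


class TestBlockProportions:
    def test_degenerate_all_deck_a(self):
        p = _participant([1] * 100)
        props, good = block_proportions(p)
        assert props.shape == (10, 4)
        assert np.array_equal(props[:, 0], np.ones(10))
        assert np.array_equal(good, np.zeros(10))

    def test_counting(self):
        p = _participant([1, 1, 1, 2, 2, 3, 3, 3, 3, 4])
        props, good = block_proportions(p)
        assert props[0].tolist() == [0.3, 0.2, 0.4, 0.1]
        assert good[0] == 0.5

    def test_rows_sum_to_one_exactly(self, rng):
        decks = rng.integers(1, 5, size=70).tolist()
        props, _ = block_proportions(_participant(decks))
        assert np.all(props.sum(axis=1) == 1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            block_proportions(ParticipantData("x", []))


class TestTrialRecord:
    def test_net_outcome_sign_convention(self):
        t = TrialRecord(1, 1, 100.0, -150.0)
        assert t.net_outcome == -50.0

    def test_positive_loss_rejected(self):
        with pytest.raises(ValueError):
            TrialRecord(1, 1, 100.0, 50.0)

    def test_trial_contiguity_enforced(self):
        with pytest.raises(ValueError, match="contiguous"):
            ParticipantData("p", [TrialRecord(2, 1, 100.0, 0.0)])


class TestDatasetIO:
    def _two_participant_dataset(self):
        p1 = _participant([1, 2, 3, 4], losses=[0.0, -1250.0, 0.0, 0.0])
        p2 = _participant([4, 4, 4], rewards=[50.0] * 3, pid="p2")
        return GroupDataset([p1, p2], name="demo")

    def test_roundtrip(self, tmp_path):
        ds = self._two_participant_dataset()
        path = tmp_path / "demo.csv"
        write_dataset(ds, path)
        back = read_dataset(path, name="demo")
        assert len(back) == 2
        for orig, readback in zip(ds, back):
            assert orig.participant_id == readback.participant_id
            assert orig.trials == readback.trials

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject,trial,deck,reward\np1,1,1,100\n")
        with pytest.raises(ValueError, match="loss"):
            read_dataset(path)

    def test_bad_deck_cites_row(self, tmp_path):
        rows = ["subject,trial,deck,reward,loss"]
        rows += [f"p1,{i},1,100,0" for i in range(1, 16)]
        rows.append("p1,16,5,100,0")
        path = tmp_path / "bad.csv"
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="row 17"):
            read_dataset(path)

    def test_non_contiguous_trials(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject,trial,deck,reward,loss\np1,1,1,100,0\np1,3,1,100,0\n"
        )
        with pytest.raises(ValueError, match="non-contiguous"):
            read_dataset(path)


def test_dataset_to_arrays_pads_and_scales():
    p1 = _participant([1, 2], losses=[0.0, -1250.0])
    p2 = _participant([3], rewards=[50.0], pid="p2")
    choices, net, n_trials = dataset_to_arrays(GroupDataset([p1, p2]))
    assert choices.shape == (2, 2)
    assert n_trials.tolist() == [2, 1]
    assert net[0, 1] == pytest.approx((100 - 1250) / 100)
    assert net[1, 0] == pytest.approx(0.5)


class TestSchemeConfig:
    def test_json_roundtrip(self, scheme, tmp_path):
        import json

        from igtbayes.igt_task import scheme_from_config, scheme_to_config

        path = tmp_path / "scheme.json"
        path.write_text(json.dumps(scheme_to_config(scheme)))
        back = scheme_from_config(path)
        assert back == scheme

    def test_yaml_roundtrip(self, scheme, tmp_path):
        import yaml

        from igtbayes.igt_task import scheme_from_config, scheme_to_config

        path = tmp_path / "scheme.yaml"
        path.write_text(yaml.safe_dump(scheme_to_config(scheme)))
        assert scheme_from_config(path) == scheme

    def test_dict_input_with_defaults(self, scheme):
        from igtbayes.igt_task import scheme_from_config, scheme_to_config

        cfg = scheme_to_config(scheme)
        del cfg["endowment"]
        back = scheme_from_config(cfg)
        assert back.endowment == 2000.0
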