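import random

import pytest

from causalpipe.errors import BlockedStateError, SamplingError
from causalpipe.learners import make_classifier
from causalpipe.self_training import (
    Instance, LoopRecord, SelfTrainConfig, SelfTrainState,
    TriggerBlockedPolicy, argument_position_policy, build_seed,
    max_confidence_policy, promote, run_grid, self_train, top_pool,
)


class _StubModel:
    """Deterministic contract-satisfying learner: memorises labelled means
    of feature 'x' and scores by distance."""

    def fit(self, X, y):
        self.centres = {}
        for row, label in zip(X, y):
            self.centres.setdefault(label, []).append(row["x"])
        self.centres = {lab: sum(v) / len(v)
                        for lab, v in self.centres.items()}
        return self

    def predict(self, X):
        out = []
        for row in X:
            scored = sorted(
                ((abs(row["x"] - c), lab) for lab, c in self.centres.items()))
            d, lab = scored[0]
            margin = (scored[1][0] - d) if len(scored) > 1 else 1.0
            out.append((lab, min(0.999, max(0.001, margin / (margin + 1)))))
        return out


def _instances(rng, n, spread=5.0):
    out = []
    for i in range(n):
        pos = rng.random() < 0.5
        x = rng.gauss(spread if pos else 0.0, 1.0)
        out.append(Instance(uid=f"i{i}", features={"x": x},
                            label="B" if pos else "O"))
    return out


def _strip(instances):
    return [Instance(uid=i.uid, features=i.features) for i in instances]


class TestSelfTrainLoop:
    def test_tau_zero_is_one_supervised_pass(self):
        rng = random.Random(0)
        labelled = _instances(rng, 40)
        pool = _strip(_instances(rng, 60))
        sup = _StubModel().fit([i.features for i in labelled],
                               [i.label for i in labelled])
        expected = [lab for lab, _ in
                    sup.predict([i.features for i in pool])]
        result = self_train(labelled, pool, _StubModel,
                            SelfTrainConfig(tau=0.0))
        assert len(result.ledger) == 1
        promoted = {i.uid: i.label for i in result.labelled
                    if i.meta.get("provenance") == "threshold-promoted"}
        assert [promoted[i.uid] for i in pool] == expected

    def test_empty_pool_equals_supervised(self):
        rng = random.Random(1)
        labelled = _instances(rng, 30)
        result = self_train(labelled, [], _StubModel, SelfTrainConfig())
        sup = _StubModel().fit([i.features for i in labelled],
                               [i.label for i in labelled])
        probe = [{"x": v} for v in (-1.0, 0.5, 4.0, 6.0)]
        assert result.model.predict(probe) == sup.predict(probe)
        assert result.ledger == []

    def test_conservation_and_termination(self):
        """Λ∪Υ ids are invariant and the loop count never exceeds the
        initial unlabelled pool size."""
        rng = random.Random(2)
        for trial in range(20):
            labelled = _instances(rng, rng.randint(4, 20))
            pool = _strip(_instances(rng, rng.randint(1, 40)))
            all_ids = {i.uid for i in labelled} | {i.uid for i in pool}
            tau = rng.choice([0.0, 0.3, 0.6, 0.9])
            result = self_train(labelled, pool, _StubModel,
                                SelfTrainConfig(tau=tau),
                                policy=max_confidence_policy)
            assert {i.uid for i in result.labelled} == all_ids
            assert len(result.ledger) <= len(pool) or not pool
            assert all(rec.promoted >= 1 for rec in result.ledger)

    def test_every_promoted_instance_carries_provenance(self):
        rng = random.Random(3)
        result = self_train(_instances(rng, 20), _strip(_instances(rng, 20)),
                            _StubModel, SelfTrainConfig(tau=0.5),
                            policy=max_confidence_policy)
        for inst in result.labelled:
            assert inst.meta["provenance"] in (
                "seed", "threshold-promoted", "heuristic-promoted")
            assert inst.label is not None

    def test_separable_data_matches_supervised_oracle(self):
        """On a 2-cluster separable set the self-trained labels agree with
        the fully supervised oracle trained on all true labels."""
        rng = random.Random(4)
        full = _instances(rng, 500, spread=6.0)
        truth = {i.uid: i.label for i in full}
        seed = full[:50]
        pool = _strip(full[50:])
        result = self_train(seed, pool,
                            lambda: make_classifier("maxent"),
                            SelfTrainConfig(tau=0.8),
                            policy=max_confidence_policy)
        agree = sum(1 for i in result.labelled if i.label == truth[i.uid])
        assert agree / len(result.labelled) >= 0.99


class TestPromote:
    def _preds(self, confs):
        return [(Instance(uid=f"p{i}", features={"x": 0.0}), "B", c)
                for i, c in enumerate(confs)]

    def test_threshold_filter_matches_brute_force(self):
        rng = random.Random(5)
        for _ in range(30):
            confs = [round(rng.random(), 3) for _ in range(rng.randint(1, 30))]
            tau = rng.random()
            preds = self._preds(confs)
            state = SelfTrainState(labelled=[],
                                   unlabelled=[p[0] for p in preds])
            record = promote(state, preds, tau, max_confidence_policy)
            expected = [c for c in confs if c > tau]
            if expected:
                assert record.promoted == len(expected)
                assert record.heuristic == 0
            else:
                assert record.promoted == 1 and record.heuristic == 1

    def test_tau_monotone_promotion(self):
        """For fixed predictions, the set promoted at a higher τ is a
        subset of the set promoted at a lower τ."""
        rng = random.Random(6)
        confs = [round(rng.random(), 3) for _ in range(50)]
        promoted = {}
        for tau in (0.2, 0.5, 0.8):
            preds = self._preds(confs)
            state = SelfTrainState(labelled=[],
                                   unlabelled=[p[0] for p in preds])
            promote(state, preds, tau, max_confidence_policy)
            promoted[tau] = {i.uid for i in state.labelled}
        assert promoted[0.8] <= promoted[0.5] <= promoted[0.2]

    def test_exact_count_moves(self):
        preds = self._preds([0.95, 0.9, 0.85, 0.2, 0.1, 0.4, 0.3, 0.25,
                             0.15, 0.05])
        state = SelfTrainState(labelled=[], unlabelled=[p[0] for p in preds])
        record = promote(state, preds, 0.8, None)
        assert record.promoted == 3
        assert len(state.labelled) == 3 and len(state.unlabelled) == 7


class TestBlockedPolicies:
    def _trigger_instance(self, uid, lemma, rules):
        f = {"L2": lemma,
             "X8.1": "VP" if "ancestor" in rules else "X",
             "X8.2": "X", "X8.3": "X",
             "C2": "ccmd" in rules, "C3": False,
             "C8": "vpcmd" in rules, "C9": False,
             "S1": "bio" in rules, "S3": False, "S6": False}
        return Instance(uid=uid, features=f)

    def test_qualifying_token_promoted_as_trigger(self):
        """A top-5% token whose lemma is in the lexicon and which
        c-commands a VP satisfies two rules and is promoted."""
        seed = [Instance(uid="s", features={"L2": "thus"}, label="B")]
        good = self._trigger_instance("good", "thus", {"ccmd", "bio"})
        # 'bio' in rules here means S1 True → rule 5 fails; lemma + ccmd pass
        others = [self._trigger_instance(f"o{i}", "gene", {"bio"})
                  for i in range(30)]
        preds = [(good, "O", 0.55)] + [(o, "O", 0.2) for o in others]
        state = SelfTrainState(labelled=seed, unlabelled=[p[0] for p in preds])
        policy = TriggerBlockedPolicy()
        record = promote(state, preds, 0.9, policy)
        assert record.heuristic == 1
        assert state.labelled[-1] is good
        assert good.label == "B"

    def test_promotes_only_top_pool_members(self):
        """Qualifying tokens outside the top 5% of confidences are not
        promoted."""
        seed = [Instance(uid="s", features={"L2": "thus"}, label="B")]
        lure = self._trigger_instance("low", "thus", {"ccmd"})
        filler = [self._trigger_instance(f"f{i}", "gene", set())
                  for i in range(40)]
        preds = [(f, "O", 0.5) for f in filler] + [(lure, "O", 0.1)]
        state = SelfTrainState(labelled=seed, unlabelled=[p[0] for p in preds])
        with pytest.raises(BlockedStateError):
            promote(state, preds, 0.9, TriggerBlockedPolicy())

    def test_fewer_than_two_rules_is_hard_error(self):
        seed = [Instance(uid="s", features={"L2": "thus"}, label="B")]
        weak = self._trigger_instance("weak", "gene", {"bio"})
        state = SelfTrainState(labelled=seed, unlabelled=[weak])
        with pytest.raises(BlockedStateError) as exc:
            promote(state, [(weak, "O", 0.3)], 0.9, TriggerBlockedPolicy())
        assert exc.value.loop == 1

    def test_rule_count(self):
        policy = TriggerBlockedPolicy()
        inst = self._trigger_instance("x", "thus", {"ancestor", "ccmd",
                                                    "vpcmd"})
        # lemma + ancestor + ccmd + vpcmd + non-biomedical = 5
        assert policy.rules_satisfied(inst, {"thus"}) == 5
        assert policy.rules_satisfied(inst, set()) == 4

    def test_argument_position_rule(self):
        initial = Instance(uid="a", features={"P1": 0})
        mid = Instance(uid="b", features={"P1": 4})
        preds = [(initial, "SS", 0.1), (mid, "DS", 0.2)]
        state = SelfTrainState(labelled=[], unlabelled=[initial, mid])
        chosen = argument_position_policy(state, preds, 1.0)
        assert dict((i.uid, lab) for i, lab in chosen) == {"a": "DS",
                                                           "b": "SS"}

    def test_top_pool_size(self):
        preds = [(Instance(uid=str(i), features={}), "O", i / 100)
                 for i in range(100)]
        pool = top_pool(preds, 0.05)
        assert len(pool) == 5
        assert min(p[2] for p in pool) >= 0.95


class TestBuildSeed:
    def _corpus(self, n_pos=40, n_neg=400):
        pos = [Instance(uid=f"p{i}", features={}, label="B")
               for i in range(n_pos)]
        neg = [Instance(uid=f"n{i}", features={}, label="O")
               for i in range(n_neg)]
        return pos + neg

    def test_full_fraction_balanced_ratio(self):
        seed = build_seed(self._corpus(), 1.0, "1:1", 3)
        labels = [i.label for i in seed]
        assert labels.count("B") == 40 and labels.count("O") == 40

    def test_half_fraction_double_ratio(self):
        seed = build_seed(self._corpus(), 0.5, "1:2", 3)
        labels = [i.label for i in seed]
        assert labels.count("B") == 20 and labels.count("O") == 40

    def test_natural_ratio_preserves_skew(self):
        seed = build_seed(self._corpus(), 0.5, "natural", 3)
        labels = [i.label for i in seed]
        assert labels.count("B") == 20 and labels.count("O") == 200

    def test_determinism(self):
        a = build_seed(self._corpus(), 0.5, "1:5", 7)
        b = build_seed(self._corpus(), 0.5, "1:5", 7)
        assert [i.uid for i in a] == [i.uid for i in b]

    def test_oversampling_rejected(self):
        with pytest.raises(SamplingError):
            build_seed(self._corpus(n_neg=30), 1.0, "1:1", 3)


class TestGrid:
    def _labelled(self, rng, n=120):
        out = []
        for i in range(n):
            pos = rng.random() < 0.3
            out.append(Instance(
                uid=f"g{i}",
                features={"x": rng.gauss(4.0 if pos else 0.0, 1.0)},
                label="B" if pos else "O"))
        return out

    def test_single_cell_single_rep(self):
        rng = random.Random(8)
        table = run_grid(self._labelled(rng), [], ["stub"],
                         taus=[0.8], fractions=[1.0], ratios=["1:1"],
                         reps=1, learner_factory=lambda name: _StubModel())
        assert len(table) == 1
        assert table.iloc[0]["runs"] == 2  # split-swap folds

    def test_reported_f_is_mean_over_runs(self):
        rng = random.Random(9)
        labelled = self._labelled(rng)
        table = run_grid(labelled, [], ["stub"], taus=[0.8],
                         fractions=[1.0], ratios=["1:1"], reps=2,
                         learner_factory=lambda name: _StubModel())
        assert table.iloc[0]["runs"] == 4
        assert 0.0 <= table.iloc[0]["F"] <= 1.0

    def test_one_row_per_grid_cell(self):
        rng = random.Random(10)
        table = run_grid(self._labelled(rng), [], ["stub"],
                         taus=[0.6, 0.9], fractions=[0.5, 1.0],
                         ratios=["1:1", "1:2"], reps=1,
                         learner_factory=lambda name: _StubModel())
        assert len(table) == 8
        assert set(table.columns) >= {"learner", "tau", "fraction", "ratio",
                                      "P", "R", "F", "loops"}
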