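"""Splits, bag sampling, Cox loss closed forms, C-index oracle, stopping rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsisurv.bags import FeatureBag
from wsisurv.model import ModelConfig
from wsisurv.nn import Tensor
from wsisurv.synth import SynthCohortSpec, generate_cohort
from wsisurv.survstats import labels_from_frame
from wsisurv.training import (SurvivalLabel, TrainConfig, concordance_index,
                              cox_loss, sample_bag, split_patients, train)


# -- splitting ----------------------------------------------------------------

@pytest.mark.parametrize("n,expected", [(10, (4, 4, 2)), (5, (2, 2, 1)),
                                        (7, (3, 3, 1)), (3, (1, 1, 1))])
def test_split_sizes_follow_largest_remainder(n, expected):
    parts = split_patients([f"p{i}" for i in range(n)], (4, 4, 2), seed=0)
    assert tuple(len(p) for p in parts) == expected


def test_split_is_partition_and_deterministic():
    pats = [f"p{i}" for i in range(23)]
    a = split_patients(pats, (4, 4, 2), seed=9)
    b = split_patients(pats, (4, 4, 2), seed=9)
    assert a == b
    flat = [p for part in a for p in part]
    assert sorted(flat) == sorted(pats)
    assert len(set(flat)) == len(pats)


def test_split_refuses_too_few_patients():
    with pytest.raises(ValueError):
        split_patients(["a", "b"], (4, 4, 2), seed=0)


# -- bag sampling -------------------------------------------------------------

def _bag(n, d=4, seed=0):
    r = np.random.default_rng(seed)
    return FeatureBag("S", "P", r.normal(size=(n, d)).astype(np.float32),
                      r.integers(0, 100, (n, 2)).astype(np.int32))


def test_sample_without_replacement_from_large_bag(rng):
    bag = _bag(600)
    sub = sample_bag(bag, 512, rng)
    assert sub.n_tiles == 512
    rows = {tuple(r) for r in sub.feats}
    assert len(rows) == 512
    src = {tuple(r) for r in bag.feats}
    assert rows <= src


def test_small_bag_passes_through_whole(rng):
    bag = _bag(100)
    sub = sample_bag(bag, 512, rng)
    assert sub is bag


def test_every_tile_seen_over_many_epochs():
    # coupon-collector check: sampling 512 of 600 per epoch covers all tiles
    bag = _bag(600)
    rng = np.random.default_rng(42)
    seen = np.zeros(600, bool)
    for _ in range(10_000):
        idx = rng.choice(600, 512, replace=False)
        seen[idx] = True
        if seen.all():
            break
    sampled_rows = {tuple(r) for r in bag.feats[seen]}
    assert seen.all() and len(sampled_rows) == 600


# -- Cox loss -----------------------------------------------------------------

def test_cox_loss_matches_closed_form_two_patients():
    loss = cox_loss(Tensor(np.zeros(2)), np.array([1.0, 2.0]), np.array([1, 1]))
    assert loss.item() == pytest.approx((np.log(2) + 0.0) / 2, abs=1e-6)


def test_cox_loss_matches_closed_form_four_patients():
    # events at t=1 (r=a) and t=3 (r=c); censored at t=2 and t=4
    a, b, c, d = 0.5, -0.3, 0.2, -0.1
    scores = np.array([a, b, c, d])
    times = np.array([1.0, 2.0, 3.0, 4.0])
    events = np.array([1, 0, 1, 0])
    expected = -0.5 * ((a - np.log(np.exp(a) + np.exp(b) + np.exp(c) + np.exp(d)))
                       + (c - np.log(np.exp(c) + np.exp(d))))
    assert cox_loss(Tensor(scores), times, events).item() == pytest.approx(expected, abs=1e-6)


def test_cox_loss_shift_invariant(rng):
    s = rng.normal(size=6)
    t = rng.uniform(1, 10, 6)
    e = np.array([1, 0, 1, 1, 0, 1])
    l0 = cox_loss(Tensor(s), t, e).item()
    l1 = cox_loss(Tensor(s + 13.7), t, e).item()
    assert l0 == pytest.approx(l1, abs=1e-10)


def test_cox_loss_vanishes_for_perfect_ranking():
    # earliest event with overwhelming score: its term -> 0
    scores = np.array([30.0, 0.0])
    loss = cox_loss(Tensor(scores), np.array([1.0, 2.0]), np.array([1, 1]))
    assert loss.item() == pytest.approx(0.0, abs=1e-6)


def test_cox_loss_gradient_matches_finite_differences(rng):
    s = rng.normal(size=8)
    t = rng.uniform(1, 20, 8)
    e = (rng.random(8) < 0.7).astype(int)
    e[0] = 1
    st_ = Tensor(s, requires_grad=True)
    cox_loss(st_, t, e).backward()
    eps = 1e-6
    for i in range(8):
        d = np.zeros(8)
        d[i] = eps
        fd = (cox_loss(Tensor(s + d), t, e).item()
              - cox_loss(Tensor(s - d), t, e).item()) / (2 * eps)
        assert st_.grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


def test_cox_loss_requires_an_event():
    with pytest.raises(ValueError):
        cox_loss(Tensor(np.zeros(3)), np.arange(1.0, 4.0), np.zeros(3, int))


# -- concordance --------------------------------------------------------------

def brute_force_cindex(scores, labels):
    num = den = 0.0
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            if li.time_months < lj.time_months and li.event == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def test_cindex_all_ties_is_half():
    labels = [SurvivalLabel(f"p{i}", t, 1) for i, t in enumerate([1, 2, 3, 4])]
    assert concordance_index(np.zeros(4), labels) == 0.5


def test_cindex_perfect_ranking_is_one():
    labels = [SurvivalLabel(f"p{i}", t, 1) for i, t in enumerate([1, 2, 3, 4])]
    assert concordance_index(np.array([4.0, 3.0, 2.0, 1.0]), labels) == 1.0


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=25, deadline=None)
def test_cindex_equals_exhaustive_pair_enumeration(seed):
    r = np.random.default_rng(seed)
    n = int(r.integers(4, 12))
    labels = [SurvivalLabel(f"p{i}", float(t), int(e))
              for i, (t, e) in enumerate(zip(r.uniform(1, 10, n),
                                             r.random(n) < 0.7))]
    if not any(l.event for l in labels):
        labels[0] = SurvivalLabel("p0", labels[0].time_months, 1)
    scores = r.normal(size=n).round(1)  # rounding forces occasional ties
    assert concordance_index(scores, labels) == pytest.approx(
        brute_force_cindex(scores, labels))


def test_cindex_undefined_without_comparable_pairs():
    labels = [SurvivalLabel("a", 1.0, 0), SurvivalLabel("b", 2.0, 0)]
    with pytest.raises(ValueError):
        concordance_index(np.array([1.0, 2.0]), labels)


# -- training loop ------------------------------------------------------------

def _tiny_training_setup(seed=0):
    spec = SynthCohortSpec(n_patients=30, feature_dim=8, tiles_per_patient_range=(5, 10),
                           signal_shift=3.0, seed=seed)
    co = generate_cohort(spec)
    bags = {b.patient_id: b for b in co.bags}
    labels = labels_from_frame(co.clinical)
    mcfg = ModelConfig(input_dim=8, embed_dim=8, n_layers=1, n_heads=2, ffn_dim=16,
                       dropout=0.0, head_hidden=(4,), seed=0)
    return bags, labels, mcfg


def test_patience_zero_trains_exactly_one_epoch():
    bags, labels, mcfg = _tiny_training_setup()
    tcfg = TrainConfig(tiles_per_bag=8, batch_size=8, lr=1e-3, max_epochs=10,
                       patience=0, seed=0)
    _, tlog = train(bags, labels, mcfg, tcfg)
    assert len(tlog.epoch_val_cindex) == 1


def test_best_checkpoint_reproduces_logged_cindex():
    from wsisurv.training import score_bags, split_patients

    bags, labels, mcfg = _tiny_training_setup()
    tcfg = TrainConfig(tiles_per_bag=8, batch_size=8, lr=1e-3, max_epochs=5,
                       patience=5, seed=0)
    splits = split_patients([l.patient_id for l in labels], tcfg.split_ratio, tcfg.seed)
    model, tlog = train(bags, labels, mcfg, tcfg, splits=splits)
    lab = {l.patient_id: l for l in labels}
    val = concordance_index(score_bags(model, [bags[p] for p in splits[1]]),
                            [lab[p] for p in splits[1]])
    assert val == pytest.approx(tlog.best_val_cindex, abs=1e-12)


def test_training_is_deterministic_given_seed():
    bags, labels, mcfg = _tiny_training_setup()
    tcfg = TrainConfig(tiles_per_bag=8, batch_size=8, lr=1e-3, max_epochs=3,
                       patience=3, seed=4)
    _, log1 = train(bags, labels, mcfg, tcfg)
    _, log2 = train(bags, labels, mcfg, tcfg)
    assert log1.epoch_losses == log2.epoch_losses
    assert log1.epoch_val_cindex == log2.epoch_val_cindex


def test_linear_model_on_true_risk_recovers_ranking():
    # 1-D features equal to the latent risk itself; a 0-layer model with no
    # regularization must align with it (positive effective slope)
    rng = np.random.default_rng(3)
    n = 120
    z = rng.normal(size=n)
    te = rng.exponential(1 / (0.05 * np.exp(1.5 * z)))
    labels = [SurvivalLabel(f"p{i}", float(te[i]), 1) for i in range(n)]
    bags = {f"p{i}": FeatureBag("s", f"p{i}", np.array([[z[i]]], np.float32),
                                np.zeros((1, 2), np.int32)) for i in range(n)}
    mcfg = ModelConfig(input_dim=1, embed_dim=2, n_layers=0, n_heads=1, ffn_dim=2,
                       dropout=0.0, head_hidden=(), head_layernorm=False, seed=1)
    tcfg = TrainConfig(tiles_per_bag=1, batch_size=64, lr=1e-2, l1_weight=0.0,
                       l2_weight=0.0, max_epochs=60, patience=60, seed=0)
    model, tlog = train(bags, labels, mcfg, tcfg)
    scores = np.array([model.forward(bags[f"p{i}"].feats.astype(float)).risk
                       for i in range(n)])
    c = concordance_index(scores, labels)
    c_true = concordance_index(z, labels)
    assert c > 0.75 and c >= c_true - 0.05
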