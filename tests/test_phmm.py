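"""Profile HMM training, forward scoring, and threshold selection."""

import numpy as np
import pytest

import ubimdd as u
from ubimdd import phmm
from ubimdd.fragment_io import AA_INDEX
from conftest import random_fragment_set


def frag(window, label=u.POSITIVE):
    n = (len(window) - 1) // 2
    return u.Fragment(window=window, n=n, label=label,
                      protein_id="p", site_position=n + 1)


# ---------------------------------------------------------------------------
# independent oracle: explicit enumeration of every state path
# ---------------------------------------------------------------------------

def enumerate_forward(emissions, background, transitions, obs):
    """Sum the probability of `obs` over all match/insert/delete paths.

    Mirrors the model architecture by brute force: begin carries the
    match transition bundle, inserts emit the background and self-loop,
    deletes are silent.  Exponential in length; fine for L <= 3.
    """
    L = len(emissions)
    T = len(obs)
    mm, mi, md = transitions["mm"], transitions["mi"], transitions["md"]
    im, ii = transitions["im"], transitions["ii"]
    dm, dd = transitions["dm"], transitions["dd"]

    def total(state, k, t):
        if state == "E":
            return 1.0 if t == T else 0.0
        acc = 0.0
        if state in ("B", "M"):
            if k == L:
                acc += (mm + md) * total("E", k, t)
            else:
                if t < T:
                    acc += mm * emissions[k][obs[t]] * total("M", k + 1, t + 1)
                acc += md * total("D", k + 1, t)
            if t < T:
                acc += mi * background[obs[t]] * total("I", k, t + 1)
        elif state == "I":
            if k == L:
                acc += im * total("E", k, t)
            elif t < T:
                acc += im * emissions[k][obs[t]] * total("M", k + 1, t + 1)
            if t < T:
                acc += ii * background[obs[t]] * total("I", k, t + 1)
        elif state == "D":
            if k == L:
                acc += (dm + dd) * total("E", k, t)
            else:
                if t < T:
                    acc += dm * emissions[k][obs[t]] * total("M", k + 1, t + 1)
                acc += dd * total("D", k + 1, t)
        return acc

    return total("B", 0, 0)


def oracle_bit_score(model, fragment):
    codes = [AA_INDEX[c] for c in fragment.core]
    start, end = fragment.pad_left, model.length - fragment.pad_right
    em = model.match_emissions[start:end]
    fwd = enumerate_forward(em, model.background, model.transitions, codes)
    null_em = np.tile(model.background, (end - start, 1))
    null = enumerate_forward(null_em, model.background, model.transitions, codes)
    return np.log2(fwd / null)


class TestTraining:
    def test_laplace_smoothing_of_a_single_fragment(self):
        model = u.build_profile_hmm(u.FragmentSet([frag("CDKGH")]), pseudocount=1.0)
        for pos, aa in enumerate("CDKGH"):
            assert model.match_emissions[pos, AA_INDEX[aa]] == pytest.approx(2 / 21)
            others = np.delete(model.match_emissions[pos], AA_INDEX[aa])
            assert np.allclose(others, 1 / 21)

    def test_emission_rows_normalized(self, small_positives):
        model = u.build_profile_hmm(small_positives)
        assert np.allclose(model.match_emissions.sum(axis=1), 1.0)
        assert model.background.sum() == pytest.approx(1.0)

    def test_model_depends_only_on_count_to_pseudocount_ratio(self):
        # duplicating every observation and the pseudocount weight leaves
        # the smoothed emissions unchanged
        single = u.build_profile_hmm(u.FragmentSet([frag("CDKGH")]), pseudocount=1.0)
        doubled = u.build_profile_hmm(
            u.FragmentSet([frag("CDKGH")] * 2), pseudocount=2.0
        )
        assert np.allclose(single.match_emissions, doubled.match_emissions)

    def test_padded_positions_fall_back_to_uniform(self):
        model = u.build_profile_hmm(u.FragmentSet([frag("-AKA-")]))
        assert np.allclose(model.match_emissions[0], 1 / 20)

    def test_negative_fragments_rejected(self):
        with pytest.raises(u.ValidationError, match="positive"):
            u.build_profile_hmm(u.FragmentSet([frag("AAKAA", u.NEGATIVE)]))


class TestBitScores:
    def test_flat_model_scores_zero_everywhere(self, small_positives):
        bg = np.full(20, 0.05)
        model = phmm.ProfileHMM(
            match_emissions=np.tile(bg, (13, 1)), background=bg
        )
        scores = u.bit_scores(model, small_positives)
        assert np.allclose(scores, 0.0, atol=1e-12)

    def test_forward_matches_path_enumeration(self, rng):
        for trial in range(25):
            alpha = np.ones(20)
            model = phmm.ProfileHMM(
                match_emissions=rng.dirichlet(alpha, size=3),
                background=rng.dirichlet(alpha),
            )
            windows = ["AKC", "-KC", "AK-", "-K-", "WKW"]
            window = windows[trial % len(windows)]
            fragment = frag(window)
            assert u.bit_score(model, fragment) == pytest.approx(
                oracle_bit_score(model, fragment), abs=1e-12
            )

    def test_position_sum_limit_of_the_match_path(self, rng):
        transitions = dict(phmm.DEFAULT_TRANSITIONS)
        transitions.update(mm=1 - 1e-9, mi=5e-10, md=5e-10)
        model = phmm.ProfileHMM(
            match_emissions=rng.dirichlet(np.ones(20), size=7),
            background=rng.dirichlet(np.ones(20)),
            transitions=transitions,
        )
        fragment = frag("ACDKGHW")
        codes = [AA_INDEX[c] for c in fragment.window]
        expected = sum(
            np.log2(model.match_emissions[p, c] / model.background[c])
            for p, c in enumerate(codes)
        )
        assert u.bit_score(model, fragment) == pytest.approx(expected, abs=1e-6)

    def test_training_fragments_outscore_random_ones(self, small_positives, rng):
        model = u.build_profile_hmm(small_positives)
        train_scores = u.bit_scores(model, small_positives)
        random_scores = u.bit_scores(model, random_fragment_set(rng, 200, n=6))
        assert train_scores.mean() > random_scores.mean()

    def test_forward_probability_is_a_probability(self, small_positives):
        model = u.build_profile_hmm(small_positives)
        scores = u.bit_scores(model, small_positives)
        assert np.all(np.isfinite(scores))

    def test_length_mismatch_rejected(self, small_positives):
        model = u.build_profile_hmm(small_positives)
        with pytest.raises(u.ValidationError, match="length"):
            u.bit_score(model, frag("AAKAA"))

    def test_unknown_residues_contribute_no_odds(self, small_positives):
        import dataclasses

        transitions = dict(phmm.DEFAULT_TRANSITIONS)
        transitions.update(mm=1 - 1e-9, mi=5e-10, md=5e-10)
        model = dataclasses.replace(
            u.build_profile_hmm(small_positives), transitions=transitions
        )
        plain = frag("ACDGHIKLMNPQW")
        masked = frag("XCDGHIKLMNPQX")
        # X adds equal mass to model and null, so only the flanking
        # columns' odds change
        delta = u.bit_score(model, plain) - u.bit_score(model, masked)
        em, bg = model.match_emissions, model.background
        expected = sum(
            np.log2(em[p, AA_INDEX[aa]] / bg[AA_INDEX[aa]])
            - np.log2(1 / 20 / (1 / 20))
            for p, aa in ((0, "A"), (12, "W"))
        )
        assert delta == pytest.approx(expected, abs=1e-6)


class TestThresholdSelection:
    def scores(self, values, label):
        # helper building fragments whose identity is irrelevant
        return u.FragmentSet([frag("AAKAA", label) for _ in values])

    def test_separable_scores_reach_perfect_accuracy(self, monkeypatch):
        fixed = iter([np.array([5.0, 6.0]), np.array([1.0, 2.0])])
        monkeypatch.setattr(phmm, "bit_scores", lambda m, f: next(fixed))
        model = u.build_profile_hmm(u.FragmentSet([frag("AAKAA")]))
        chosen = phmm.select_threshold(
            model, self.scores([5, 6], u.POSITIVE), self.scores([1, 2], u.NEGATIVE)
        )
        assert 2.0 < chosen.threshold < 5.0
        assert chosen.objective_value == 1.0

    def test_overlapping_scores_take_best_achievable_accuracy(self, monkeypatch):
        fixed = iter([np.array([2.0, 1.0]), np.array([1.5, 0.0])])
        monkeypatch.setattr(phmm, "bit_scores", lambda m, f: next(fixed))
        model = u.build_profile_hmm(u.FragmentSet([frag("AAKAA")]))
        chosen = phmm.select_threshold(
            model, self.scores([2, 1], u.POSITIVE), self.scores([1.5, 0], u.NEGATIVE)
        )
        assert chosen.objective_value == pytest.approx(0.75)
        # accuracy ties at 0.5 and 1.75; MCC ties too; lower wins
        assert chosen.threshold == pytest.approx(0.5)

    def test_empty_inputs_rejected(self, small_positives):
        model = u.build_profile_hmm(small_positives)
        with pytest.raises(u.ValidationError):
            phmm.select_threshold(model, small_positives, u.FragmentSet())


def test_model_serialization_round_trips_bit_exact(small_positives):
    model = u.build_profile_hmm(small_positives)
    restored = phmm.model_from_text(phmm.model_to_text(model))
    assert np.array_equal(model.match_emissions, restored.match_emissions)
    assert np.array_equal(model.background, restored.background)
    assert model.transitions == restored.transitions
    rescored = u.bit_scores(restored, small_positives)
    assert np.array_equal(u.bit_scores(model, small_positives), rescored)
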