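"""GY94 rate matrix and transition-probability properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flightsel as fs
from flightsel.model import RateMatrix, mean_rate


def random_freqs(seed, code):
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.ones(code.n_states))
    return pi


class TestRateMatrix:
    def test_unit_mean_rate_and_zero_row_sums(self, equal_freqs):
        q = fs.build_rate_matrix(2.0, 0.5, equal_freqs)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert np.isclose(-(equal_freqs * np.diag(q)).sum(), 1.0)

    def test_neutral_equal_entries(self, code, equal_freqs):
        # kappa=1, omega=1, equal pi: every allowed single-step rate equal
        q = fs.build_rate_matrix(1.0, 1.0, equal_freqs)
        off = q[~np.eye(code.n_states, dtype=bool)]
        nonzero = off[off > 0]
        assert np.allclose(nonzero, nonzero[0])

    def test_omega_zero_kills_nonsynonymous(self, code, equal_freqs):
        q = fs.build_rate_matrix(2.0, 0.0, equal_freqs)
        _, _, synonymous = code.single_step_structure()
        diff_pos, _, _ = code.single_step_structure()
        nonsyn = (diff_pos >= 0) & ~synonymous
        assert np.all(q[nonsyn] == 0.0)

    def test_transition_transversion_entry_ratio(self, code, equal_freqs):
        # TTT->TTC is a synonymous transition, TTT->TTA a nonsynonymous
        # transversion: their rate ratio is kappa/omega
        q = fs.build_rate_matrix(2.0, 0.5, equal_freqs)
        i, jc, ja = code.index["TTT"], code.index["TTC"], code.index["TTA"]
        assert np.isclose(q[i, jc] / q[i, ja], 2.0 / 0.5)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_time_reversibility(self, seed):
        code = fs.get_code()
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(np.ones(code.n_states))
        kappa = float(rng.uniform(0.5, 10))
        omega = float(rng.uniform(0.01, 5))
        q = fs.build_rate_matrix(kappa, omega, pi)
        assert np.allclose(pi[:, None] * q, (pi[:, None] * q).T, atol=1e-12)

    def test_invalid_inputs(self, equal_freqs):
        with pytest.raises(ValueError):
            fs.build_rate_matrix(-1.0, 0.5, equal_freqs)
        with pytest.raises(ValueError):
            fs.build_rate_matrix(2.0, -0.5, equal_freqs)
        with pytest.raises(ValueError):
            fs.build_rate_matrix(2.0, 0.5, equal_freqs[:-1])

    def test_mean_rate_linear_in_omega(self, equal_freqs):
        m0 = mean_rate(2.0, 0.0, equal_freqs)
        m1 = mean_rate(2.0, 1.0, equal_freqs)
        m4 = mean_rate(2.0, 4.0, equal_freqs)
        assert np.isclose(m4, m0 + 4 * (m1 - m0))


class TestTransitionProbabilities:
    def test_identity_at_zero(self, code, equal_freqs):
        q = fs.build_rate_matrix(2.0, 0.3, equal_freqs)
        assert np.allclose(
            fs.transition_probabilities(q, 0.0, equal_freqs), np.eye(code.n_states)
        )

    def test_rows_are_distributions(self, equal_freqs):
        rng = np.random.default_rng(5)
        pi = rng.dirichlet(np.ones(len(equal_freqs)))
        q = fs.build_rate_matrix(3.0, 0.7, pi)
        p = fs.transition_probabilities(q, 0.3, pi)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(p >= 0)

    def test_short_time_series_expansion(self, code, equal_freqs):
        q = fs.build_rate_matrix(2.0, 0.5, equal_freqs)
        t = 1e-4
        p = fs.transition_probabilities(q, t, equal_freqs)
        assert np.allclose(p, np.eye(code.n_states) + q * t, atol=5 * t**2)

    def test_negative_time_rejected(self, equal_freqs):
        q = fs.build_rate_matrix(2.0, 0.5, equal_freqs)
        with pytest.raises(ValueError):
            fs.transition_probabilities(q, -0.1, equal_freqs)

    def test_eigendecomposition_matches_expm(self, equal_freqs):
        from scipy.linalg import expm

        rng = np.random.default_rng(11)
        pi = rng.dirichlet(np.ones(len(equal_freqs)))
        q = fs.build_rate_matrix(2.5, 0.2, pi)
        p_eig = RateMatrix(q=q, pi=pi).with_decomposition().probs(0.7)
        assert np.allclose(p_eig, expm(q * 0.7), atol=1e-10)


class TestCodonFrequencies:
    def test_equal(self, code):
        pi = fs.codon_frequencies(None, "equal", code)
        assert np.allclose(pi, 1.0 / code.n_states)

    def test_f3x4_valid_distribution(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">A\nTTTGGGAAACCC\n>B\nTTCGGAAAGCCA\n")
        aln = fs.read_codon_alignment(p)
        for method in ("F1x4", "F3x4"):
            pi = fs.codon_frequencies(aln, method)
            assert np.isclose(pi.sum(), 1.0)
            assert np.all(pi > 0)

    def test_branch_site_proportions(self):
        om = fs.BranchSiteOmega(p0=0.6, p1=0.2, omega0=0.1, omega2=3.0)
        props = om.proportions
        assert np.isclose(props.sum(), 1.0)
        # p2a/p2b split the remainder proportionally to p0:p1
        assert np.isclose(props[2] / props[3], 0.6 / 0.2)

    def test_branch_site_invalid(self):
        with pytest.raises(ValueError):
            fs.BranchSiteOmega(p0=0.6, p1=0.2, omega0=1.5, omega2=3.0)
        with pytest.raises(ValueError):
            fs.BranchSiteOmega(p0=0.6, p1=0.2, omega0=0.1, omega2=0.5)
        with pytest.raises(ValueError):
            fs.BranchSiteOmega(p0=0.0, p1=0.2, omega0=0.1, omega2=2.0)
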