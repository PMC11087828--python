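"""Credible region budget, structure-set construction, membership, projection."""

import numpy as np
import pytest

from ctuq.prox import SolverConfig, grad2d
from ctuq.structure_sets import (
    StructureSet,
    build_structure_set,
    compute_eta_alpha,
    membership,
    project_structure_set,
)


def percentile_oracle(samples, q):
    """Linear-interpolation percentile computed from first principles."""
    xs = sorted(samples)
    pos = (len(xs) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


class TestEtaAlpha:
    def test_monotone_decreasing_in_alpha(self):
        vals = [compute_eta_alpha(10.0, 256, a) for a in (0.01, 0.05, 0.2)]
        assert vals[0] > vals[1] > vals[2]

    def test_closed_form_plug_in(self):
        # psi + N + sqrt(16 N log(3/alpha)) evaluated independently
        alpha, n, psi = 0.3, 1, 0.0
        got = compute_eta_alpha(psi, n, alpha)
        assert got == pytest.approx(1.0 + np.sqrt(16.0 * np.log(10.0)))

    def test_never_below_psi_plus_n(self):
        for alpha in (0.001, 0.5, 0.999):
            assert compute_eta_alpha(7.0, 64, alpha) >= 7.0 + 64

    def test_verbatim_reading(self):
        a = 0.01
        got = compute_eta_alpha(5.0, 128, a, reading="verbatim")
        assert got == pytest.approx(5.0 + 128 + 16 * 128 * np.log(3 / a))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            compute_eta_alpha(1.0, 10, 1.5)


class TestBuildStructureSet:
    def _image_with_mask(self, fill):
        img = np.full((16, 16), fill, dtype=float)
        mask = np.zeros((16, 16), dtype=bool)
        mask[7:9, 7:9] = True
        return img, mask

    def test_constant_neighborhood_degenerate_histogram(self):
        img, mask = self._image_with_mask(0.7)
        s = build_structure_set(img, mask, dilation_width=2)
        assert s.mu_pix == pytest.approx(0.7)
        assert s.r_pix == pytest.approx(0.0)
        assert s.mu_grad == pytest.approx(0.0)
        assert s.r_grad == pytest.approx(0.0)

    def test_percentile_rule_against_oracle(self):
        img, mask = self._image_with_mask(0.0)
        s_probe = build_structure_set(img + 1.0, mask, dilation_width=2)
        samples = np.arange(1.0, 12.0)  # 11 neighborhood-sized sample values
        med = percentile_oracle(samples, 50)
        r_expected = max(percentile_oracle(samples, 60) - med,
                         med - percentile_oracle(samples, 40))
        # feed the same samples through the public path: place them in the
        # annulus of a small image
        img2 = np.zeros((16, 16))
        mask2 = np.zeros((16, 16), dtype=bool)
        mask2[8, 8] = True
        from ctuq.structure_sets import _percentile_radius
        mu, r = _percentile_radius(samples)
        assert mu == pytest.approx(med)
        assert r == pytest.approx(r_expected)
        assert s_probe.r_pix == pytest.approx(0.0)

    def test_mask_and_neighborhood_disjoint(self):
        img, mask = self._image_with_mask(0.5)
        s = build_structure_set(img, mask, dilation_width=3)
        assert not (s.mask & s.neighborhood).any()
        assert s.neighborhood.any()

    def test_empty_mask_rejected(self):
        img = np.zeros((8, 8))
        with pytest.raises(ValueError, match="empty"):
            build_structure_set(img, np.zeros((8, 8), dtype=bool))


class TestMembership:
    def test_negative_pixel_flags_intensity_set(self):
        img = np.full((10, 10), 0.5)
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:6, 4:6] = True
        s = build_structure_set(img, mask, dilation_width=2)
        bad = img.copy()
        bad[0, 0] = -1.0
        ok, viol = membership(bad, s, tol=1e-6)
        assert not ok
        assert viol["nonneg"] > 0

    def test_projection_output_is_member(self, rng):
        img = rng.random((12, 12)) * 0.5 + 0.2
        mask = np.zeros((12, 12), dtype=bool)
        mask[5:8, 5:8] = True
        img[mask] = 0.05  # a dark defect
        s = build_structure_set(img, mask, dilation_width=2)
        proj, diag = project_structure_set(img, s,
                                           SolverConfig(max_iters=5000))
        assert diag.converged
        ok, viol = membership(proj, s, tol=1e-3)
        assert ok, viol


class TestProjectStructureSet:
    def _defect_case(self, rng):
        img = np.full((12, 12), 0.6) + rng.normal(0, 0.01, (12, 12))
        img = np.clip(img, 0, None)
        mask = np.zeros((12, 12), dtype=bool)
        mask[5:8, 5:8] = True
        img[mask] *= 0.2
        s = build_structure_set(img, mask, dilation_width=2)
        return img, mask, s

    def test_member_is_fixed_point(self, rng):
        img = np.full((12, 12), 0.4)
        mask = np.zeros((12, 12), dtype=bool)
        mask[5:7, 5:7] = True
        s = build_structure_set(img, mask, dilation_width=2)
        proj, diag = project_structure_set(img, s,
                                           SolverConfig(max_iters=3000))
        assert diag.converged
        np.testing.assert_allclose(proj, img, atol=1e-4)

    def test_single_pixel_clamp_closed_form(self):
        img = np.full((9, 9), 0.5)
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        img[4, 4] = 0.05
        s = StructureSet(
            mask=mask,
            neighborhood=np.pad(np.zeros((7, 7), bool), 1, constant_values=True),
            mu_pix=0.5, r_pix=0.1, mu_grad=0.0, r_grad=np.inf,
        )
        proj, diag = project_structure_set(img, s,
                                           SolverConfig(max_iters=5000))
        assert diag.converged
        # masked pixel clamps into [mu - r, mu + r] n [0, inf): 0.05 -> 0.4
        assert proj[4, 4] == pytest.approx(0.4, abs=2e-3)
        untouched = ~mask
        np.testing.assert_allclose(proj[untouched], img[untouched], atol=1e-4)

    def test_projection_optimality_sampling(self, rng):
        img, mask, s = self._defect_case(rng)
        proj, diag = project_structure_set(img, s,
                                           SolverConfig(max_iters=8000))
        assert diag.converged
        d_star = np.linalg.norm(proj - img)
        ns = s.n_structure
        hits = 0
        for _ in range(1000):
            z = img.copy()
            z[s.mask] = np.clip(
                s.mu_pix + rng.uniform(-1, 1, ns) * s.r_pix, 0, None
            )
            ok, _ = membership(z, s, tol=1e-6)
            if not ok:
                continue
            hits += 1
            assert d_star <= np.linalg.norm(z - img) + 1e-6
        assert hits > 0  # the sampler did exercise the feasible set

    def test_idempotent_and_nonexpansive(self, rng):
        img, mask, s = self._defect_case(rng)
        cfg = SolverConfig(max_iters=8000)
        p1, _ = project_structure_set(img, s, cfg)
        p2, _ = project_structure_set(p1, s, cfg)
        np.testing.assert_allclose(p2, p1, atol=5e-3)
        other = img + rng.normal(0, 0.05, img.shape)
        q1, _ = project_structure_set(other, s, cfg)
        assert (np.linalg.norm(p1 - q1)
                <= np.linalg.norm(img - other) + 5e-3)

    def test_shrinking_radii_never_decreases_distance(self, rng):
        img, mask, s = self._defect_case(rng)
        cfg = SolverConfig(max_iters=8000)
        dists = []
        for shrink in (1.0, 0.5, 0.1):
            s2 = StructureSet(
                mask=s.mask, neighborhood=s.neighborhood,
                mu_pix=s.mu_pix, r_pix=s.r_pix * shrink,
                mu_grad=s.mu_grad, r_grad=s.r_grad * shrink,
            )
            proj, _ = project_structure_set(img, s2, cfg)
            dists.append(np.linalg.norm(proj - img))
        assert dists[0] <= dists[1] + 1e-3
        assert dists[1] <= dists[2] + 1e-3
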