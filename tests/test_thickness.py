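"""Density profiles, FWHM thickness extraction and protein-proximal thinning."""

import numpy as np
import pytest

import scramblescan as ss
from scramblescan.thickness import DensityProfile, _xy_min_image_dist2


def _profile(edges, density, n_frames=1):
    return DensityProfile(
        z_bin_edges=np.asarray(edges, float),
        density=np.asarray(density, float),
        selection_descriptor="test",
        n_frames=n_frames,
    )


@pytest.fixture(scope="module")
def system():
    spec = ss.SyntheticBilayerSpec(
        n_lipids_per_leaflet=64,
        duration_ns=5.0,
        n_replicas=1,
        protein=ss.ProteinSpec(),
        seed=30,
    )
    sys_ = ss.simulate(spec)
    return sys_, next(sys_.frames(0))


class TestProximalBeads:
    def test_zero_cutoff_selects_nothing(self, system):
        sys_, frame = system
        assert len(ss.proximal_lipid_beads(frame, sys_.topology, cutoff=0.0)) == 0

    def test_matches_exhaustive_pairwise_oracle(self, system):
        sys_, frame = system
        topo = sys_.topology
        got = set(ss.proximal_lipid_beads(frame, topo, cutoff=1.0).tolist())

        # O(N^2) oracle with explicit xy minimum-image distances
        prot = topo.protein_indices
        lip = topo.lipid_indices
        close_resids = set()
        for i in lip:
            for j in prot:
                d = frame.positions[i] - frame.positions[j]
                for k in (0, 1):
                    d[k] -= frame.box[k] * round(d[k] / frame.box[k])
                if np.dot(d, d) < 1.0:
                    close_resids.add(topo.resids[i])
                    break
        expected = {
            int(i)
            for i in lip
            if topo.resids[i] in close_resids and topo.names[i] not in ("NC3", "PO4")
        }
        assert got == expected

    def test_no_protein_is_an_error(self):
        spec = ss.SyntheticBilayerSpec(n_lipids_per_leaflet=8, duration_ns=2.0, n_replicas=1, seed=1)
        sys_ = ss.simulate(spec)
        with pytest.raises(ss.SelectionError, match="bulk"):
            ss.proximal_lipid_beads(next(sys_.frames(0)), sys_.topology)


class TestDensityProfile:
    def _frames(self, z_values, n=200, box_z=10.0):
        pos = np.zeros((n, 3))
        pos[:, 2] = z_values
        yield ss.Frame(time_ns=2000.0, positions=pos, box=np.array([5.0, 5.0, box_z]))

    def test_midplane_spike(self):
        frames = self._frames(np.full(200, 5.0))
        profile = ss.density_profile(frames, np.arange(200), np.arange(200))
        # all mass lands in one bin touching z = 0
        peak = profile.density.argmax()
        assert abs(profile.z_centers[peak]) <= profile.bin_width / 2 + 1e-12
        assert profile.density[peak] * profile.bin_width == pytest.approx(200.0)

    def test_uniform_slab_is_flat(self):
        rng = np.random.default_rng(0)
        n = 200_000
        z = 5.0 + rng.uniform(-2.0, 2.0, n)
        profile = ss.density_profile(self._frames(z, n=n), np.arange(n), np.arange(n))
        inside = np.abs(profile.z_centers) < 1.8
        assert profile.density[inside] == pytest.approx(n / 4.0, rel=0.05)

    def test_normalization_invariant(self):
        rng = np.random.default_rng(1)
        n = 5000
        z = 5.0 + rng.normal(0, 1.0, n)
        profile = ss.density_profile(self._frames(z, n=n), np.arange(n), np.arange(n))
        assert profile.density.sum() * profile.bin_width == pytest.approx(n, rel=1e-6)

    def test_empty_selection_errors(self):
        with pytest.raises(ss.AnalysisError, match="empty"):
            ss.density_profile(
                self._frames(np.full(10, 5.0), n=10), np.arange(10), np.array([], dtype=int)
            )


class TestThicknessFromProfile:
    def test_rectangular_profile(self):
        edges = np.arange(-5.0, 5.0 + 1e-9, 0.1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        density = np.where(np.abs(centers) < 1.5, 8.0, 0.0)
        assert ss.thickness_from_profile(_profile(edges, density)) == pytest.approx(3.0, abs=1e-9)

    def test_triangular_profile(self):
        # grid aligned so one bin center sits exactly at the apex
        edges = np.arange(-5.05, 5.05 + 1e-9, 0.1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        density = np.clip(2.0 - np.abs(centers), 0.0, None)  # peak 2 at 0, base 4 nm
        assert ss.thickness_from_profile(_profile(edges, density)) == pytest.approx(2.0, abs=1e-9)

    def test_gaussian_edged_slab_closed_form(self):
        # plateau 1 for |z|<a, Gaussian shoulders exp(-(|z|-a)^2/(2 s^2));
        # half max at |z| = a + s*sqrt(2 ln 2)
        a, s = 1.2, 0.3
        edges = np.arange(-5.0, 5.0 + 1e-9, 0.01)
        centers = 0.5 * (edges[:-1] + edges[1:])
        density = np.where(
            np.abs(centers) < a, 1.0, np.exp(-((np.abs(centers) - a) ** 2) / (2 * s * s))
        )
        expected = 2 * (a + s * np.sqrt(2 * np.log(2)))
        got = ss.thickness_from_profile(_profile(edges, density))
        assert got == pytest.approx(expected, abs=1e-3)

    def test_multimodal_profile_is_ambiguous(self):
        edges = np.arange(-5.0, 5.0 + 1e-9, 0.1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        density = np.where(np.abs(np.abs(centers) - 2.0) < 0.5, 4.0, 0.0)  # two slabs
        with pytest.raises(ss.AnalysisError, match="4"):
            ss.thickness_from_profile(_profile(edges, density))

    def test_invariant_under_translation_and_reflection(self):
        rng = np.random.default_rng(2)
        n = 100_000
        z = 5.0 + rng.uniform(-1.7, 1.7, n)

        def one(zv, box_z=10.0):
            pos = np.zeros((n, 3))
            pos[:, 2] = zv
            frame = ss.Frame(time_ns=2000.0, positions=pos, box=np.array([5.0, 5.0, box_z]))
            profile = ss.density_profile(iter([frame]), np.arange(n), np.arange(n))
            return ss.thickness_from_profile(profile)

        t0 = one(z)
        assert one(z + 1.234, box_z=14.0) == pytest.approx(t0, abs=1e-9)
        assert one(10.0 - z) == pytest.approx(t0, abs=1e-9)


class TestThinning:
    def test_identical_profiles_give_zero(self):
        spec = ss.SyntheticBilayerSpec(
            n_lipids_per_leaflet=100,
            duration_ns=2500.0,
            frame_interval_ns=5.0,
            n_replicas=1,
            protein=ss.ProteinSpec(),
            local_thinning_nm=0.0,
            seed=31,
        )
        sys_ = ss.simulate(spec)
        sel = ss.select_lipids(sys_.topology)
        result, _, _ = ss.membrane_thinning(
            sys_.frames(0), sys_.topology, sel, equilibration_ns=2000.0
        )
        assert result.thinning == pytest.approx(0.0, abs=0.1)

    def test_imposed_thinning_recovered(self):
        """Generator imposes 0.3 nm local thinning; the profile pipeline must
        recover it within two bin widths."""
        spec = ss.SyntheticBilayerSpec(
            n_lipids_per_leaflet=400,
            duration_ns=2500.0,
            frame_interval_ns=5.0,
            n_replicas=1,
            protein=ss.ProteinSpec(),
            local_thinning_nm=0.3,
            seed=32,
        )
        sys_ = ss.simulate(spec)
        sel = ss.select_lipids(sys_.topology)
        result, local_p, bulk_p = ss.membrane_thinning(
            sys_.frames(0), sys_.topology, sel, equilibration_ns=2000.0
        )
        assert result.bulk_thickness > result.local_thickness > 0
        assert result.thinning == pytest.approx(0.3, abs=0.2)


class TestRateThinningCorrelation:
    def test_independent_rate_and_thinning_uncorrelated(self):
        """Systems built with independent scrambling rates and thinning must
        show no pooled correlation (the two quantities are decoupled)."""
        rng = np.random.default_rng(40)
        rates, thinnings = [], []
        for seed in range(12):
            for k in range(20):
                lam = rng.uniform(0.0, 5.0)
                spec = ss.SyntheticBilayerSpec(
                    n_lipids_per_leaflet=8,
                    duration_ns=4000.0,
                    n_replicas=1,
                    flip_rate_per_us=lam,
                    seed=int(rng.integers(2**31)),
                )
                traces, ledger = ss.simulate_traces(spec)
                events = ss.detect_all(traces, ledger.initial_leaflets)
                binned = ss.bin_events(events, 4000.0, replicas=[0])
                rates.append(ss.summarize(binned).mean)
                # independently imposed thinning ground truth
                thinnings.append(rng.normal(0.2, 0.05))
        r, p = ss.rate_thinning_correlation(rates, thinnings)
        assert abs(r) < 0.25  # n = 240 independent pairs; |r| ~ 4 SE bound
        assert p > 1e-4

    def test_perfect_correlation_detected(self):
        x = np.arange(10.0)
        r, p = ss.rate_thinning_correlation(x, 0.1 * x + 1.0)
        assert r == pytest.approx(1.0)


def test_xy_min_image_wraps_only_xy():
    a = np.array([[0.1, 0.1, 0.0]])
    b = np.array([[4.9, 4.9, 3.0]])
    d2 = _xy_min_image_dist2(a, b, np.array([5.0, 5.0, 5.0]))
    assert d2[0, 0] == pytest.approx(0.2**2 + 0.2**2 + 3.0**2)
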