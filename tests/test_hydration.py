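"""Water occupancy grids, hydration-site extraction, trajectory I/O."""

import numpy as np
import pytest

from fepkit import (Box, FrameSet, Sphere, ValidationError, hydration_sites,
                    occupancy_map, synth_water_trajectory)
from fepkit.hydration import (read_water_frames, write_dx, write_sites_csv,
                              write_sites_pdb, write_water_pdb,
                              write_water_xyz)

BOX10 = Box((0.0, 0.0, 0.0), (10.0, 10.0, 10.0))


def brute_force_occupancy(frames, origin, spacing, dims):
    """Naive double-loop recount oracle."""
    presence = np.zeros(dims, dtype=int)
    for f in frames.frames:
        seen = set()
        for p in f:
            idx = tuple(int(np.floor((p[d] - origin[d]) / spacing))
                        for d in range(3))
            if all(0 <= idx[d] < dims[d] for d in range(3)):
                seen.add(idx)
        for idx in seen:
            presence[idx] += 1
    return presence / frames.n_frames


class TestOccupancyMap:
    def test_single_fixed_water_fills_one_voxel(self):
        frames = FrameSet([np.array([[3.2, 4.7, 5.1]])] * 20)
        grid = occupancy_map(frames, spacing=1.0, region=BOX10)
        assert np.count_nonzero(grid.occupancy == 1.0) == 1
        assert grid.occupancy.max() == 1.0
        idx = np.unravel_index(np.argmax(grid.occupancy), grid.dims)
        assert idx == (3, 4, 5)

    def test_partial_presence_counts_frames(self):
        present = [np.array([[2.5, 2.5, 2.5]])] * 8
        absent = [np.empty((0, 3))] * 2
        grid = occupancy_map(FrameSet(present + absent), region=BOX10)
        assert grid.occupancy.max() == pytest.approx(0.8)

    def test_matches_brute_force_recount(self, rng):
        frames = FrameSet([rng.uniform(0, 10, size=(5, 3))
                           for _ in range(40)])
        grid = occupancy_map(frames, spacing=1.0, region=BOX10)
        oracle = brute_force_occupancy(frames, grid.origin, grid.spacing,
                                       grid.dims)
        np.testing.assert_array_equal(grid.occupancy, oracle)

    def test_frame_order_invariance(self, rng):
        frames = [rng.uniform(0, 10, size=(3, 3)) for _ in range(15)]
        g1 = occupancy_map(FrameSet(frames), region=BOX10)
        g2 = occupancy_map(FrameSet(frames[::-1]), region=BOX10)
        np.testing.assert_array_equal(g1.occupancy, g2.occupancy)

    def test_occupancy_bounded(self, rng):
        frames = FrameSet([rng.uniform(0, 10, size=(30, 3))
                           for _ in range(10)])
        grid = occupancy_map(frames, region=BOX10)
        assert grid.occupancy.min() >= 0.0
        assert grid.occupancy.max() <= 1.0

    def test_sphere_masks_outside_voxels(self):
        frames = FrameSet([np.array([[1.0, 1.0, 1.0], [5.0, 5.0, 5.0]])] * 5)
        grid = occupancy_map(frames, region=Sphere((5.0, 5.0, 5.0), 2.0))
        # corner water lies outside the sphere: no occupied voxel there
        centers = grid.voxel_centers()
        occupied = centers[grid.occupancy > 0]
        dists = np.linalg.norm(occupied - np.array([5.0, 5.0, 5.0]), axis=1)
        assert (dists <= 2.0).all()

    def test_finer_grid_stays_inside_coarse_coverage(self, rng):
        frames = FrameSet([rng.uniform(0, 10, size=(4, 3))
                           for _ in range(10)])
        coarse = occupancy_map(frames, spacing=1.0, region=BOX10)
        fine = occupancy_map(frames, spacing=0.5, region=BOX10)
        fine_centers = fine.voxel_centers()[fine.occupancy > 0]
        idx = np.floor((fine_centers - coarse.origin) / coarse.spacing
                       ).astype(int)
        assert (coarse.occupancy[tuple(idx.T)] > 0).all()

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValidationError, match="frame"):
            FrameSet([])
        frames = FrameSet([np.zeros((1, 3))])
        with pytest.raises(ValidationError, match="spacing"):
            occupancy_map(frames, spacing=0.0, region=BOX10)


class TestHydrationSites:
    def test_empty_grid_gives_no_sites(self):
        grid = occupancy_map(FrameSet([np.empty((0, 3))] * 3), region=BOX10)
        assert hydration_sites(grid) == []

    def test_single_voxel_site_at_voxel_center(self):
        frames = FrameSet([np.array([[3.4, 4.6, 5.2]])] * 10)
        grid = occupancy_map(frames, region=BOX10)
        (site,) = hydration_sites(grid, threshold=0.8)
        assert site.position == (3.5, 4.5, 5.5)
        assert site.peak_occupancy == 1.0
        assert site.n_voxels == 1

    def test_two_planted_tethered_waters_recovered(self):
        sites_in = [((3.5, 5.5, 5.5), 0.3, 1.0),
                    ((9.5, 5.5, 5.5), 0.3, 0.95)]
        frames = synth_water_trajectory(sites_in, n_frames=500,
                                        n_bulk_waters=1,
                                        region=Box((0, 0, 0), (12, 12, 12)),
                                        seed=7)
        grid = occupancy_map(frames, spacing=1.0,
                             region=Box((0, 0, 0), (12, 12, 12)))
        sites = hydration_sites(grid, threshold=0.8)
        assert len(sites) == 2
        found = sorted(s.position for s in sites)
        for est, true in zip(found, [(3.5, 5.5, 5.5), (9.5, 5.5, 5.5)]):
            assert np.linalg.norm(np.array(est) - np.array(true)) < 0.5

    def test_presence_probability_reflected_in_occupancy(self):
        frames = synth_water_trajectory([((5.0, 5.0, 5.0), 0.0, 0.5)],
                                        n_frames=2000, n_bulk_waters=0,
                                        region=BOX10, seed=3)
        grid = occupancy_map(frames, region=BOX10)
        # binomial: 0.5 +/- ~3.4 sd at n=2000
        assert grid.occupancy.max() == pytest.approx(0.5, abs=0.04)

    def test_synth_trajectory_deterministic(self):
        kw = dict(sites=[((5.0, 5.0, 5.0), 0.2, 0.9)], n_frames=10,
                  n_bulk_waters=2, region=BOX10, seed=11)
        f1 = synth_water_trajectory(**kw)
        f2 = synth_water_trajectory(**kw)
        for a, b in zip(f1.frames, f2.frames):
            np.testing.assert_array_equal(a, b)


class TestTrajectoryIO:
    def _frames(self):
        return synth_water_trajectory(
            [((5.0, 5.0, 5.0), 0.2, 1.0)], n_frames=4, n_bulk_waters=2,
            region=BOX10, seed=2)

    @pytest.mark.parametrize("writer,suffix", [
        (write_water_pdb, ".pdb"), (write_water_xyz, ".xyz")])
    def test_roundtrip(self, tmp_path, writer, suffix):
        frames = self._frames()
        path = tmp_path / f"waters{suffix}"
        writer(frames, path)
        back = read_water_frames(path)
        assert back.n_frames == frames.n_frames
        for a, b in zip(back.frames, frames.frames):
            np.testing.assert_allclose(a, b, atol=5e-3)

    def test_dx_writer_roundtrips_through_text(self, tmp_path):
        grid = occupancy_map(self._frames(), region=BOX10)
        path = tmp_path / "occ.dx"
        write_dx(grid, path)
        text = path.read_text()
        nx, ny, nz = grid.dims
        assert f"gridpositions counts {nx} {ny} {nz}" in text
        vals = []
        for line in text.splitlines():
            if line.startswith(("#", "object", "origin", "delta",
                                "attribute", "component")):
                continue
            vals.extend(float(v) for v in line.split())
        np.testing.assert_allclose(np.array(vals),
                                   grid.occupancy.ravel(), atol=1e-6)

    def test_sites_outputs(self, tmp_path):
        grid = occupancy_map(self._frames(), region=BOX10)
        sites = hydration_sites(grid, threshold=0.8)
        write_sites_pdb(sites, tmp_path / "sites.pdb")
        write_sites_csv(sites, tmp_path / "sites.csv")
        assert (tmp_path / "sites.pdb").read_text().count("HETATM") == len(sites)
        lines = (tmp_path / "sites.csv").read_text().strip().splitlines()
        assert lines[0].startswith("x_A,")
        assert len(lines) == len(sites) + 1
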