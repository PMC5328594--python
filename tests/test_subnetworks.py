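import numpy as np
import pytest

from mesomap import (
    ImagingStack,
    assign_to_centers,
    partition_motifs,
    single_event_motifs,
    spontaneous_motifs,
    subnetwork_subtract,
)
from mesomap.subnetworks import MotifSet


@pytest.fixture(scope="module")
def toy_stack():
    rng = np.random.default_rng(8)
    return ImagingStack(100.0 + rng.random((300, 4, 4)), 10.0)


class TestSingleEventMotifs:
    def test_single_trigger_equals_event_peak(self, toy_stack):
        ms = single_event_motifs(toy_stack, np.array([100]))
        assert ms.n_motifs == 1
        # oracle: explicit per-pixel loop
        f = 100
        fs = 10.0
        pre, post = -30, 30
        expect = np.empty((4, 4))
        for r in range(4):
            for c in range(4):
                f0 = toy_stack.data[f - 30:f, r, c].mean()
                win = (toy_stack.data[f - 10:f + 11, r, c] - f0) / f0
                expect[r, c] = win[np.abs(win).argmax()]
        assert np.allclose(ms.vectors[0].reshape(4, 4), expect, atol=1e-6)

    def test_three_event_brute_force(self, toy_stack):
        triggers = np.array([60, 120, 200])
        ms = single_event_motifs(toy_stack, triggers)
        for i, f in enumerate(triggers):
            one = single_event_motifs(toy_stack, np.array([f]))
            assert np.allclose(ms.vectors[i], one.vectors[0])

    def test_clipped_events_dropped(self, toy_stack):
        ms = single_event_motifs(toy_stack, np.array([2, 150]))
        assert ms.n_motifs == 1 and ms.n_dropped == 1


class TestSpontaneousMotifs:
    def test_count_formula(self, toy_stack):
        ms = spontaneous_motifs(toy_stack)
        # full needed window: baseline start (-3 s) to window end (+3 s)
        W = int(6.0 * toy_stack.frame_rate_hz)
        assert ms.n_motifs == toy_stack.n_frames - W + 1

    def test_constant_stack_zero_motifs(self):
        stack = ImagingStack(np.full((250, 3, 3), 50.0), 10.0)
        ms = spontaneous_motifs(stack)
        assert np.allclose(ms.vectors, 0.0)

    def test_exclusion_radius(self, toy_stack):
        full = spontaneous_motifs(toy_stack)
        excl = spontaneous_motifs(toy_stack, exclude_frames=np.array([150]),
                                  exclusion_radius=5)
        assert excl.n_motifs == full.n_motifs - 11


class TestPartitionAssign:
    def planted_motifs(self, n_per=40, seed=0):
        rng = np.random.default_rng(seed)
        templates = np.zeros((4, 16))
        for j in range(4):
            templates[j, j * 4:(j + 1) * 4] = 1.0
        vecs, labels = [], []
        for j in range(4):
            for _ in range(n_per):
                vecs.append(templates[j] + 0.05 * rng.standard_normal(16))
                labels.append(j)
        return MotifSet(vectors=np.stack(vecs), frame_shape=(4, 4),
                        origin="spike_triggered",
                        event_frames=np.arange(4 * n_per)), np.array(labels)

    def test_planted_partition_purity(self):
        motifs, truth = self.planted_motifs()
        part = partition_motifs(motifs, k=4, seed=0)
        # purity: best mapping of clusters to planted templates
        purity = 0
        for j in range(4):
            members = truth[part.labels == j]
            if members.size:
                purity += np.bincount(members).max()
        assert purity / motifs.n_motifs >= 0.95

    def test_k1_center_is_mean(self):
        motifs, _ = self.planted_motifs(n_per=10)
        part = partition_motifs(motifs, k=1, seed=0)
        assert np.allclose(part.centers[0], motifs.vectors.mean(axis=0), atol=1e-8)

    def test_duplication_invariance(self):
        motifs, _ = self.planted_motifs(n_per=15)
        doubled = MotifSet(vectors=np.vstack([motifs.vectors, motifs.vectors]),
                           frame_shape=(4, 4), origin="spike_triggered",
                           event_frames=np.arange(2 * motifs.n_motifs))
        c1 = np.sort(partition_motifs(motifs, k=4, seed=0).centers, axis=0)
        c2 = np.sort(partition_motifs(doubled, k=4, seed=0).centers, axis=0)
        assert np.allclose(c1, c2, atol=1e-8)

    def test_assign_center_itself(self):
        motifs, _ = self.planted_motifs(n_per=10)
        part = partition_motifs(motifs, k=4, seed=0)
        centers_set = MotifSet(vectors=part.centers, frame_shape=(4, 4),
                               origin="spontaneous",
                               event_frames=np.arange(4))
        assigned = assign_to_centers(centers_set, part.centers)
        assert assigned.labels.tolist() == [0, 1, 2, 3]

    def test_assign_matches_brute_force(self, rng):
        motifs, _ = self.planted_motifs(n_per=10, seed=3)
        part = partition_motifs(motifs, k=4, seed=0)
        assigned = assign_to_centers(motifs, part.centers)
        for v, lab in zip(motifs.vectors, assigned.labels):
            d = [np.linalg.norm(v - c) for c in part.centers]
            assert lab == int(np.argmin(d))

    def test_equidistant_tie_low_index(self):
        centers = np.array([[0.0, 0.0], [2.0, 0.0]])
        point = MotifSet(vectors=np.array([[1.0, 0.0]]), frame_shape=(1, 2),
                         origin="spontaneous", event_frames=np.arange(1))
        assert assign_to_centers(point, centers).labels.tolist() == [0]


class TestSubtract:
    def test_identical_sets_zero_diff(self):
        rng = np.random.default_rng(4)
        vecs = rng.standard_normal((40, 16))
        spike = MotifSet(vectors=vecs, frame_shape=(4, 4), origin="spike_triggered",
                         event_frames=np.arange(40))
        spike = partition_motifs(spike, k=2, seed=0)
        spont = MotifSet(vectors=vecs.copy(), frame_shape=(4, 4), origin="spontaneous",
                         event_frames=np.arange(40))
        spont = assign_to_centers(spont, spike.centers)
        out = subnetwork_subtract(spike, spont)
        for dm in out["diff_maps"].values():
            assert np.allclose(dm, 0.0, atol=1e-10)

    def test_conservation_weighted_mean(self):
        rng = np.random.default_rng(5)
        vecs = rng.standard_normal((60, 16))
        spike = partition_motifs(
            MotifSet(vectors=vecs, frame_shape=(4, 4), origin="spike_triggered",
                     event_frames=np.arange(60)), k=4, seed=0)
        # spike-count-weighted mean of partition means = all-spike mean, exactly
        weighted = np.zeros(16)
        for j in range(4):
            members = vecs[spike.labels == j]
            weighted += members.shape[0] * members.mean(axis=0)
        assert np.allclose(weighted / 60, vecs.mean(axis=0), atol=1e-12)

    def test_k1_reduces_to_global_difference(self):
        rng = np.random.default_rng(6)
        sv = rng.standard_normal((30, 16))
        pv = rng.standard_normal((50, 16))
        spike = partition_motifs(
            MotifSet(vectors=sv, frame_shape=(4, 4), origin="spike_triggered",
                     event_frames=np.arange(30)), k=1, seed=0)
        spont = assign_to_centers(
            MotifSet(vectors=pv, frame_shape=(4, 4), origin="spontaneous",
                     event_frames=np.arange(50)), spike.centers)
        out = subnetwork_subtract(spike, spont)
        assert np.allclose(out["diff_maps"][0],
                           (sv.mean(axis=0) - pv.mean(axis=0)).reshape(4, 4))

    def test_mismatched_centers_rejected(self):
        rng = np.random.default_rng(7)
        a = partition_motifs(MotifSet(vectors=rng.standard_normal((20, 16)),
                                      frame_shape=(4, 4), origin="spike_triggered",
                                      event_frames=np.arange(20)), k=2, seed=0)
        b = partition_motifs(MotifSet(vectors=rng.standard_normal((20, 16)),
                                      frame_shape=(4, 4), origin="spontaneous",
                                      event_frames=np.arange(20)), k=2, seed=1)
        with pytest.raises(ValueError, match="centers"):
            subnetwork_subtract(a, b)


class TestMeanIdentity:
    def test_mean_single_event_maps_conserved(self, toy_stack):
        # the all-spike map of this module is the mean of the per-event
        # peak maps; partitioning must conserve it exactly
        triggers = np.arange(40, 260, 10)
        ms = single_event_motifs(toy_stack, triggers)
        part = partition_motifs(ms, k=3, seed=0)
        out = subnetwork_subtract(
            part, assign_to_centers(ms, part.centers))
        total = np.zeros(16)
        n = 0
        for j, entry in out["report"].items():
            total += entry["n_spike"] * out["spike_means"][j].ravel()
            n += entry["n_spike"]
        assert np.allclose(total / n, out["all_spike_mean"].ravel(), atol=1e-12)
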