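"""Synthetic cohort generator: genealogies, SGA events, array signals."""

import numpy as np
import pytest
from scipy.stats import kstest

import sgaclock as sc
from sgaclock.cohort import (
    CohortConfig,
    GenomeModel,
    TrueEventLog,
    make_probe_map,
    simulate_array_signals,
    simulate_genealogy,
    simulate_individual,
    simulate_sga_events,
)
from sgaclock.demography import LogisticDemography
from sgaclock.likelihood import EpochModel
from sgaclock.trees import SampledTree, TreeNode


@pytest.fixture(scope="module")
def demography():
    return LogisticDemography(K=5e4, N_t=3e4, T_r=600.0)


class TestGenealogy:
    def test_constant_size_pairwise_coalescent(self):
        # K reached long before sampling: 2-tip coalescence times follow
        # the standard exponential with mean N
        d = LogisticDemography(K=20.0, N_t=19.95, T_r=3650.0)
        rng = np.random.default_rng(1)
        ages = np.array(
            [-simulate_genealogy(d, [(0.0, ["a", "b"])], rng).mrca.time
             for _ in range(2000)]
        )
        assert kstest(ages, "expon", args=(0, 20.0)).pvalue > 0.01

    def test_serial_tips_force_older_root(self, demography):
        rng = np.random.default_rng(2)
        tree = simulate_genealogy(demography, [(0.0, ["a"]), (5.0, ["b"])], rng)
        assert tree.mrca.time < 5.0
        assert tree.luca.time < tree.mrca.time

    def test_seeded_determinism(self, demography):
        sampling = [(0.0, ["a", "b"]), (4.0, ["c", "d"])]
        one = simulate_genealogy(demography, sampling, 42).to_newick()
        two = simulate_genealogy(demography, sampling, 42).to_newick()
        assert one == two

    def test_coalescences_not_older_than_initiation(self, demography):
        rng = np.random.default_rng(3)
        tree = simulate_genealogy(
            demography, [(0.0, [f"t{i}" for i in range(8)])], rng
        )
        for node in tree.internal_nodes():
            assert -node.time <= demography.T_init

    def test_tip_times_match_sampling(self, demography):
        tree = simulate_genealogy(
            demography, [(0.0, ["a", "b"]), (6.0, ["c"])], 5
        )
        times = {t.name: t.time for t in tree.tips()}
        assert times == {"a": 0.0, "b": 0.0, "c": 6.0}


class TestSgaEvents:
    def _tree(self):
        a = TreeNode("a", 0.0)
        b = TreeNode("b", 0.0)
        root = TreeNode(time=-10.0)
        root.add_child(a)
        root.add_child(b)
        luca = TreeNode("LUCA", -12.0)
        luca.add_child(root)
        tree = SampledTree(luca)
        for i, n in enumerate(tree.postorder()):
            if not n.is_leaf and n.name is None:
                n.name = f"n{i}"
        return tree

    def test_zero_rates_give_empty_matrix(self):
        ep = EpochModel("off_on", 5.0, 1e-5, 1e-5)
        m, log = simulate_sga_events(self._tree(), ep, GenomeModel(), 1)
        # prior lower bound is 1e-5 events/genome/year: essentially none
        assert m.n_characters == len(log.events)
        assert m.n_characters <= 1

    def test_poisson_event_count_on_single_branch(self):
        # branch entirely in the off epoch: counts are Poisson(lam * t)
        lam, t = 2.0, 10.0
        ep = EpochModel("off_on", 50.0, lam, 0.1)
        rng = np.random.default_rng(4)
        tree = self._tree()
        counts = []
        for _ in range(400):
            _, log = simulate_sga_events(tree, ep, GenomeModel(), rng)
            counts.append(
                sum(1 for e in log.events if e.branch == "a")
            )
        mean = np.mean(counts)
        se = np.sqrt(lam * t / len(counts))
        assert abs(mean - lam * t) < 3 * se

    def test_carriers_are_subtree_leaves(self, default_individual):
        ind = default_individual
        below = {}
        for node in ind.tree.postorder():
            if node.is_leaf:
                below[node.name] = frozenset([node.name])
            else:
                below[node.name] = frozenset().union(
                    *(below[c.name] for c in node.children)
                )
        for ev in ind.event_log.events:
            assert ind.event_log.carriers[ev.event_id] == below[ev.branch]

    def test_irreversibility_in_truth_matrix(self, default_individual):
        # no character is present in an ancestor's carrier set but absent
        # in a descendant: carriers are exactly subtree leaf sets, so each
        # matrix column must equal the union of its events' subtrees
        ind = default_individual
        m = ind.truth_matrix
        for j, char in enumerate(m.characters):
            carriers = {
                tip for ev in ind.event_log.events if ev.character == char
                for tip in ind.event_log.carriers[ev.event_id]
            }
            got = {m.biopsy_ids[i] for i in np.flatnonzero(m.data[:, j])}
            assert got == carriers

    def test_rate_bookkeeping(self, demography):
        # total events / branch-years converges to the epoch rate
        lam_off, lam_on = 4.0, 1.0
        ep = EpochModel("off_on", 6.0, lam_off, lam_on)
        rng = np.random.default_rng(6)
        n_off = n_on = 0
        t_off = t_on = 0.0
        for _ in range(90):
            tree = simulate_genealogy(
                demography,
                [(0.0, ["a", "b", "c"]), (6.0, ["d", "e"]), (12.0, ["f", "g"])],
                rng,
            )
            _, log = simulate_sga_events(tree, ep, GenomeModel(), rng)
            for _, t0, t1 in tree.branches():
                d_first = max(0.0, min(t1, 6.0) - t0)
                t_off += d_first
                t_on += (t1 - t0) - d_first
            n_off += sum(1 for e in log.events if e.time <= 6.0)
            n_on += sum(1 for e in log.events if e.time > 6.0)
        assert t_off > 1e4  # law-of-large-numbers regime
        assert n_off / t_off == pytest.approx(lam_off, rel=0.05)
        # the on epoch has fewer branch-years; allow 3-sigma Poisson slack
        se_on = np.sqrt(lam_on * t_on) / t_on
        assert abs(n_on / t_on - lam_on) < 3 * se_on


class TestArraySignals:
    def _noiseless(self, state, haplotype=1, genotype_focus=1):
        genome = GenomeModel(chromosomes={"chr1": 1_000_000})
        probes = make_probe_map(genome, 600, np.random.default_rng(0))
        tip = TreeNode("t", 0.0)
        other = TreeNode("u", 0.0)
        root = TreeNode(time=-5.0)
        root.add_child(tip)
        root.add_child(other)
        luca = TreeNode("LUCA", -6.0)
        luca.add_child(root)
        tree = SampledTree(luca)
        from sgaclock.cohort import SgaEvent

        ev = SgaEvent(0, "t", -1.0, "chr1", 0, 1_000_000, state, haplotype)
        log = TrueEventLog([ev], {0: frozenset(["t"])})
        sig = simulate_array_signals(
            log, tree, probes, np.random.default_rng(1),
            noise_sd=0.0, dye_bias=0.5, control_id="blood",
        )
        het = probes["genotype"].to_numpy() == 1
        return sig, het

    def test_single_gain_canonical_levels(self):
        sig, het = self._noiseless("AAB")
        df = sig["t"]
        r = df["R"].to_numpy()
        baf = df["BAF"].to_numpy()
        assert np.allclose(np.log2(r / 1.0), np.log2(1.5))
        mbaf = np.abs(baf[het] - 0.5) * 2
        assert np.allclose(mbaf, 1.0 / 3.0)

    def test_single_loss_canonical_levels(self):
        sig, het = self._noiseless("A")
        df = sig["t"]
        assert np.allclose(np.log2(df["R"].to_numpy() / 1.0), -1.0)
        baf_het = df["BAF"].to_numpy()[het]
        assert set(np.round(baf_het, 9)) <= {0.0, 1.0}

    def test_copy_neutral_loh_canonical_levels(self):
        sig, het = self._noiseless("AA")
        df = sig["t"]
        assert np.allclose(np.log2(df["R"].to_numpy()), 0.0)
        mbaf = np.abs(df["BAF"].to_numpy()[het] - 0.5) * 2
        assert np.allclose(mbaf, 1.0)

    def test_dye_bias_shifts_het_median(self, small_individual):
        ind = small_individual
        control = ind.signals[ind.control_id]
        het = ind.probes["genotype"].to_numpy() == 1
        med = np.median(control["BAF"].to_numpy()[het])
        assert med == pytest.approx(0.53, abs=0.01)

    def test_control_carries_no_events(self, small_individual):
        ind = small_individual
        control = ind.signals[ind.control_id]
        # diploid everywhere: R fluctuates around 1
        assert np.median(control["R"]) == pytest.approx(1.0, abs=0.02)

    def test_mixture_fraction_bounds(self):
        genome = GenomeModel(chromosomes={"chr1": 1000})
        probes = make_probe_map(genome, 10, 0)
        log = TrueEventLog([], {})
        tip = TreeNode("t", 0.0)
        o = TreeNode("u", 0.0)
        root = TreeNode(time=-1.0)
        root.add_child(tip)
        root.add_child(o)
        luca = TreeNode("LUCA", -2.0)
        luca.add_child(root)
        with pytest.raises(ValueError):
            simulate_array_signals(
                log, SampledTree(luca), probes, 0, mixture_fraction=0.6
            )


class TestIndividualBundle:
    def test_determinism_full_bundle(self):
        cfg = CohortConfig(n_probes=5000, n_biopsies=4, n_timepoints=2)
        a = simulate_individual(cfg, 9, with_signals=True)
        b = simulate_individual(cfg, 9, with_signals=True)
        assert a.tree.to_newick() == b.tree.to_newick()
        assert np.array_equal(a.truth_matrix.data, b.truth_matrix.data)
        for sid in a.signals:
            assert np.allclose(a.signals[sid]["BAF"], b.signals[sid]["BAF"])

    def test_metadata_contract(self, default_individual):
        ind = default_individual
        statuses = [
            (m.sample_time, m.nsaid_status)
            for m in sorted(ind.meta.values(), key=lambda m: m.sample_time)
            if not m.is_control
        ]
        # NSAID status changes exactly once across ordered endoscopies
        seq = [s for _, s in statuses]
        changes = sum(1 for x, y in zip(seq, seq[1:]) if x != y)
        assert changes == 1
        controls = [m for m in ind.meta.values() if m.is_control]
        assert len(controls) == 1
        assert ind.config.t_switch == pytest.approx(7.5)
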