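"""Ground-truth correctness and statistical behavior of the simulator."""

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pytest

from dictycomp.io_formats import DICTYOSTELIDS, SPECIES_CODES
from dictycomp.simulate import (
    DICTYOSTELIA_STEM,
    STAGES,
    SimulationConfig,
    generate_dataset,
    inject_lgt,
    make_donor_pool,
    simulate_architecture,
    simulate_expression,
    simulate_family,
    true_ortholog_pairs,
)


def _identity(a, b):
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestSimulateFamily:
    def test_zero_rates_one_gene_per_species_all_orthologs(self):
        cfg = SimulationConfig(dup_rate=0, loss_rate=0, seed=1)
        fam = simulate_family(cfg, np.random.default_rng(1), "F")
        species = sorted(r.species for r in fam.records)
        assert species == sorted(SPECIES_CODES)
        n = len(fam.records)
        assert len(fam.truth.ortholog_pairs) == n * (n - 1) // 2

    def test_zero_substitution_rate_identical_sequences(self):
        cfg = SimulationConfig(dup_rate=0, loss_rate=0, sub_rate=0.0, seed=2)
        fam = simulate_family(cfg, np.random.default_rng(2), "F")
        seqs = {r.sequence for r in fam.records}
        assert len(seqs) == 1

    def test_ortholog_relation_symmetric_and_no_self(self):
        cfg = SimulationConfig(dup_rate=0.3, loss_rate=0.1, seed=3)
        rng = np.random.default_rng(3)
        for i in range(20):
            fam = simulate_family(cfg, rng, f"F{i}")
            for pair in fam.truth.ortholog_pairs:
                assert len(pair) == 2  # frozenset: symmetric by construction

    def test_event_replay_oracle(self):
        """Ground-truth orthologs equal an independent LCA-replay.

        Replays the pruned history bottom-up: a pair is orthologous iff
        the node where the two genes' lineages first meet is a
        speciation (or the root).
        """
        cfg = SimulationConfig(dup_rate=0.2, loss_rate=0.1, seed=4)
        rng = np.random.default_rng(4)
        for i in range(50):
            fam = simulate_family(cfg, rng, f"F{i}")
            root = fam.truth.history

            # independent replay: collect (pair -> meeting-node kind)
            def descend(node):
                if node.kind == "leaf":
                    return {node.gene_id}
                sets = [descend(c) for c in node.children]
                if node.kind in ("speciation", "root"):
                    for x in range(len(sets)):
                        for y in range(x + 1, len(sets)):
                            for a in sets[x]:
                                for b in sets[y]:
                                    oracle.add(frozenset((a, b)))
                return set().union(*sets)

            oracle: set = set()
            descend(root)
            assert oracle == fam.truth.ortholog_pairs

    def test_birth_process_expectation(self):
        """Mean copies per tip matches exp(dup_rate * depth) with no loss."""
        cfg = SimulationConfig(dup_rate=0.1, loss_rate=0.0, seq_length=10, seed=5)
        rng = np.random.default_rng(5)
        n_fam = 2000
        counts = {sp: [] for sp in SPECIES_CODES}
        for i in range(n_fam):
            fam = simulate_family(cfg, rng, f"F{i}")
            per = {sp: 0 for sp in SPECIES_CODES}
            for r in fam.records:
                per[r.species] += 1
            for sp in SPECIES_CODES:
                counts[sp].append(per[sp])
        depth = {"DD": 1.8, "EH": 0.6}
        for sp, d in depth.items():
            arr = np.array(counts[sp], dtype=float)
            expected = math.exp(cfg.dup_rate * d)
            se = arr.std(ddof=1) / math.sqrt(n_fam)
            assert abs(arr.mean() - expected) < 3 * se + 1e-12


class TestInjectLGT:
    def test_stem_transfer_zero_dup_gives_five_flagged(self):
        cfg = SimulationConfig(dup_rate=0, loss_rate=0, seed=6)
        rng = np.random.default_rng(6)
        fam = simulate_family(cfg, rng, "F")
        pool = make_donor_pool(cfg, rng, "F")
        inject_lgt(fam, pool, cfg, rng)
        assert len(fam.truth.lgt_genes) == 5
        species = sorted(r.species for r in fam.records if r.id in fam.truth.lgt_genes)
        assert species == sorted(DICTYOSTELIDS)

    def test_terminal_branch_transfer_single_flag(self):
        cfg = SimulationConfig(dup_rate=0, loss_rate=0, seed=7)
        rng = np.random.default_rng(7)
        fam = simulate_family(cfg, rng, "F")
        pool = make_donor_pool(cfg, rng, "F")
        inject_lgt(fam, pool, cfg, rng, target_branch="DD")
        assert len(fam.truth.lgt_genes) == 1
        (gid,) = fam.truth.lgt_genes
        assert gid.split("_")[1] == "DD"

    def test_empty_donor_pool_rejected(self):
        cfg = SimulationConfig(seed=8)
        rng = np.random.default_rng(8)
        fam = simulate_family(cfg, rng, "F")
        pool = make_donor_pool(cfg, rng, "F")
        pool.prokaryotes = []
        with pytest.raises(ValueError, match="empty donor pool"):
            inject_lgt(fam, pool, cfg, rng)

    def test_flagged_genes_closer_to_donor_than_to_natives(self):
        """Transferred genes resemble the donor, not the native homologs."""
        cfg = SimulationConfig(dup_rate=0, loss_rate=0, seed=9)
        rng = np.random.default_rng(9)
        donor_vs_native = []
        for i in range(100):
            fam = simulate_family(cfg, rng, f"F{i}")
            natives = {r.id: r.sequence for r in fam.records}
            pool = make_donor_pool(cfg, rng, f"F{i}")
            donor_seq = "".join(
                "ACDEFGHIKLMNPQRSTVWY"[c] for c in pool.donor_codes)
            inject_lgt(fam, pool, cfg, rng)
            for r in fam.records:
                if r.id in fam.truth.lgt_genes:
                    id_donor = _identity(r.sequence, donor_seq)
                    id_native = max(_identity(r.sequence, s)
                                    for s in natives.values())
                    donor_vs_native.append(id_donor - id_native)
        assert np.mean(donor_vs_native) > 0
        assert np.mean(np.array(donor_vs_native) > 0) > 0.95


class TestExpressionSim:
    def test_no_divergence_no_noise_profiles_identical(self):
        cfg = SimulationConfig(dup_rate=0, loss_rate=0, expr_divergence_prob=0,
                               nb_dispersion=0.0, library_sigma=0.0, seed=10)
        rng = np.random.default_rng(10)
        fam = simulate_family(cfg, rng, "F")
        rows = simulate_expression(fam, cfg, rng)
        from dictycomp.expression import build_series
        profiles = {}
        for sp in DICTYOSTELIDS:
            sub = [r for r in rows if r["species"] == sp]
            s = build_series("g", sp, [r["raw"] for r in sub],
                             [r["total_reads"] for r in sub],
                             [r["avg_read_length"] for r in sub])
            profiles[sp] = np.round(s.percent_of_max, 0)
        ref = profiles["DD"]
        for sp in DICTYOSTELIDS:
            assert np.allclose(profiles[sp], ref, atol=1.0)

    def test_forced_shift_on_one_species(self):
        cfg = SimulationConfig(dup_rate=0, loss_rate=0, seed=11)
        rng = np.random.default_rng(11)
        fam = simulate_family(cfg, rng, "F")
        simulate_expression(fam, cfg, rng, forced_clade=("one_species", ("DD",)))
        assert fam.truth.expression_pattern == "one_species"
        assert fam.truth.divergent_species == ("DD",)

    def test_library_scaling_invariance_of_expected_percent(self):
        # scaling total reads and raw counts by 10x leaves the
        # normalized ratio structure, hence percent-of-max, unchanged
        from dictycomp.expression import build_series
        raw = [10, 40, 80, 40, 10, 5, 1]
        s1 = build_series("g", "DD", raw, [1e6] * 7, [100] * 7)
        s2 = build_series("g", "DD", [10 * r for r in raw], [1e7] * 7, [100] * 7)
        assert s1.percent_of_max == pytest.approx(s2.percent_of_max)


class TestArchitectureSim:
    def test_zero_gain_loss_all_identical(self):
        cfg = SimulationConfig(dup_rate=0, loss_rate=0, arch_gain_prob=0,
                               arch_loss_prob=0, seed=12)
        rng = np.random.default_rng(12)
        fam = simulate_family(cfg, rng, "F")
        archs = simulate_architecture(fam, cfg, rng)
        assert len({tuple(a) for a in archs.values()}) == 1
        assert all(fam.truth.arch_conserved.values())

    def test_forced_loss_on_dd_branch(self):
        cfg = SimulationConfig(dup_rate=0, loss_rate=0, arch_gain_prob=0,
                               arch_loss_prob=0, seed=13)
        rng = np.random.default_rng(13)
        fam = simulate_family(cfg, rng, "F")
        archs = simulate_architecture(fam, cfg, rng,
                                      root_arch=["PA14", "EGF"],
                                      forced_loss_branches={"DD"})
        dd = [a for g, a in archs.items() if "_DD_" in g][0]
        others = [a for g, a in archs.items() if "_DD_" not in g]
        assert len(dd) == 1
        assert all(a == ["PA14", "EGF"] for a in others)
        assert not fam.truth.arch_conserved[[g for g in archs if "_DD_" in g][0]]

    def test_conserved_fraction_closed_form(self):
        """P(family fully conserved) = (1-p)^(2 * n_branches)."""
        p = 0.05
        cfg = SimulationConfig(dup_rate=0, loss_rate=0, arch_gain_prob=p,
                               arch_loss_prob=p, seq_length=10, seed=14)
        rng = np.random.default_rng(14)
        n_fam = 2000
        conserved = 0
        for i in range(n_fam):
            fam = simulate_family(cfg, rng, f"F{i}")
            simulate_architecture(fam, cfg, rng)
            conserved += all(fam.truth.arch_conserved.values())
        # rooted 8-leaf species tree: 14 branches
        expected = (1 - p) ** (2 * 14)
        se = math.sqrt(expected * (1 - expected) / n_fam)
        assert abs(conserved / n_fam - expected) < 3 * se


class TestGenerateDataset:
    def test_seed_determinism_sha256(self, tmp_path):
        cfg = SimulationConfig(n_families=10, seed=42, lgt_prob=0.3)
        m1 = generate_dataset(cfg, tmp_path / "a")
        m2 = generate_dataset(cfg, tmp_path / "b")
        for name in m1["files"]:
            assert m1["files"][name]["sha256"] == m2["files"][name]["sha256"]

    def test_family_count_exact(self, tmp_path):
        cfg = SimulationConfig(n_families=100, seed=43, seq_length=10)
        generate_dataset(cfg, tmp_path / "d")
        fams = set()
        with open(tmp_path / "d" / "truth_expression.tsv") as fh:
            next(fh)
            for line in fh:
                fams.add(line.split("\t")[0])
        assert len(fams) == 100

    def test_zero_lgt_prob_no_flags(self, tmp_path):
        cfg = SimulationConfig(n_families=30, seed=44, lgt_prob=0.0,
                               seq_length=10)
        generate_dataset(cfg, tmp_path / "d")
        with open(tmp_path / "d" / "truth_lgt.tsv") as fh:
            assert len(fh.readlines()) == 1  # header only

    def test_manifest_lists_files_with_rows(self, tmp_path):
        cfg = SimulationConfig(n_families=5, seed=45, seq_length=10)
        manifest = generate_dataset(cfg, tmp_path / "d")
        assert "expression.tsv" in manifest["files"]
        listed = json.loads((tmp_path / "d" / "manifest.json").read_text())
        assert listed["n_families"] == 5


def test_cross_process_seed_determinism(tmp_path):
    """The bundle is byte-identical when generated in a fresh process."""
    import subprocess
    import sys
    code = (
        "from dictycomp.simulate import SimulationConfig, generate_dataset;"
        f"generate_dataset(SimulationConfig(n_families=5, seed=77), r'{tmp_path}/x')"
    )
    subprocess.run([sys.executable, "-c", code], check=True)
    cfg = SimulationConfig(n_families=5, seed=77)
    generate_dataset(cfg, tmp_path / "y")
    for f in sorted((tmp_path / "x").iterdir()):
        a = hashlib.sha256(f.read_bytes()).hexdigest()
        b = hashlib.sha256((tmp_path / "y" / f.name).read_bytes()).hexdigest()
        assert a == b, f.name
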